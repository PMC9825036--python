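cluster,y,x1,x2
0,1.7761775821444972,0.75045119580645725,-1.3021795068623181
0,-0.10902435565609858,0.94056471639121386,0.12784040316728537
0,0.53288399066647885,-1.9510351886538364,-0.31624259234358221
1,2.0719404243803279,0.066030697561216045,-0.049925910986252896
1,2.5436297199416722,1.1272412069680329,-0.18486236354526056
1,2.6579060795025331,0.4675093422520456,-0.68092954440394138
1,0.48981686188440832,-0.85929246288323824,1.2225413386740303
1,3.916321739824121,0.36875078408249884,-0.15452948206880215
1,0.92348110218873969,-0.9588826008289989,-0.42832782216310722
1,1.6753644232300515,0.87845030130727253,-0.35213355048822959
2,2.3796329672909078,1.1289722927208916,0.23216132306671977
2,-0.23789054245038921,-0.11394745765487507,0.11668580914072822
2,0.45488732132352172,-0.84015647696252804,0.21868859672901295
2,-0.21016863095166988,-0.82448121569123956,0.87142877794818985
2,0.87712976019456024,0.65059278782470109,0.22359554877468227
2,0.92294163746281899,0.74325417120344228,0.67891356307189488
2,3.0820428433411777,0.54315426830519498,0.067579069488891461
2,-0.060293834744280295,-0.6655097072886943,0.28911939868998415
3,-1.1708319845508761,-1.6828697716158048,0.79334723519992523
3,0.55921734155727054,-0.33488502998577485,-0.34872507224843757
3,1.1127726934374338,0.16275306510500559,-0.46235179266456716
3,1.6848582174825684,0.58622233135927815,0.85797588125715385
3,2.2320494986271728,0.71122657979285497,-0.19130432488161489
4,1.1258554537161816,0.15853969107671423,-0.36305384656507178
4,1.84258058328632,0.62559039396733673,-0.38173789399832908
4,1.992178034839136,-0.3093465397202384,-1.1958396455890397
4,1.247843155321106,0.45677523755741145,0.48697248078558181
4,0.68972182931750936,-0.66192594106665126,-0.46940234020272387
5,1.225107593740727,-0.079718210906399051,-0.90547905536006079
5,-0.74513821588457663,-1.6873344339580298,-0.3781625540393897
5,-1.3559509375674508,-1.4471124724230873,1.2992282977860654
5,1.209990520902843,-1.3226996123544024,-0.35626397106142593
5,-2.0699352789932508,-0.99724682760148176,0.73751556846708655
5,2.1272259136889851,0.3997742267234366,-0.93361768000987699
6,-0.44948396083766284,-1.4460578543884546,-1.023497492621865
6,-0.10359726027594252,0.072129507713869515,0.17927563495631615
6,-0.72380961653291487,-0.52949270906380241,0.21999668397176517
6,-0.71731173108884194,0.23267621135470395,1.3591875752404365
6,-1.3903390449443269,0.021852145523442879,0.83511124591457853
6,1.7940535717371777,1.6017788913209154,0.35687105914950934
6,-0.86903279722901172,-0.23935562747302427,1.4633028912195618
7,0.26056629230374051,-1.0155790812075416,-0.98953812003186414
7,3.0458904023961937,0.31351384745019528,-2.1320462807313092
7,0.47945890481587178,0.83812656789438111,0.2677114623438358
7,1.6075997083538711,1.9967308916917865,-0.81294109531032599
7,0.87107951162000696,2.9138624660073296,-0.41535726017968533
7,-0.86028456552010701,0.41440943327599639,-0.61209679905980807
8,2.8168272440334148,1.7679299135798829,-0.72522606453575322
8,-0.82654595336077152,0.13027452147288585,2.1284697324351645
8,2.0754470422646114,0.98273951102305757,-0.82138667922438613
8,-0.60749638817903473,-0.49929559853915206,0.83848920373634495
8,1.543672530252197,-1.1849437664170246,-0.90292717808702638
8,-0.71506980224735361,-0.96511676223237186,0.9315730128742441
9,-1.9179974457569084,-1.2779375743196193,0.21938250136385634
9,2.3306002174989504,0.17258791772211948,-0.41092723083373717
9,1.8928169226802547,1.5790912564104349,1.1062887100598888
9,-0.17789201552552134,0.15999161357343825,0.42875643846161349
9,-1.4064747360480714,-0.11863832610988256,1.535755991995992
9,1.7224063540055998,0.28582613960254288,0.18323443722190613
9,0.79016695592597608,1.3060017417068248,-1.2244690317205003
10,0.013989624402540424,-0.3946051228595896,1.4074818613137168
10,0.46773694763912332,-0.0051218667200712961,0.090584906901745546
10,-0.4296894674939441,-0.16344289852451258,0.64393879327685788
10,2.3167686651089605,0.33757454879893356,-2.0501721010310225
11,1.3651100029971874,0.91590254235601309,-0.32767309436196085
11,-1.3618192952046555,-1.326392717739564,1.0027578253046041
11,0.16049051539308107,0.030631492594417446,0.53811543700392606
11,-0.26998047577024986,-0.48416943333357848,1.3373981074427437
12,-2.5703056433884219,0.090489781627874216,1.8768446112816701
12,0.55536898821300218,0.22822833013890514,-0.85324335055882006
12,2.153615868256622,2.5174740375339204,-0.2873833615491761
13,0.96367329774056709,-0.72908383774360852,-0.87686077816758823
13,3.3087625242224012,-0.65414644006779654,-0.094262554252556988
13,4.9611175399893241,-2.1472890297386549,-1.7577283913566313
13,1.6442487797479373,-0.16266592054490767,-1.4670452453909906
13,-0.87934167980751066,-1.0624144118595631,2.1292471120282981
13,2.8302860748096377,-0.52943942736607374,-1.287422581274031
14,0.62447509121109157,-0.24527784594210975,-0.13382296451604114
14,1.3411439688508993,0.77733757606174403,-1.3748958083699818
14,1.2873463079012379,0.43476607446661863,-0.23817374397466523
14,1.4456335271550005,-0.37615607123009925,-0.26638749000895512
15,-1.7341341081537054,0.35175640839920347,1.5733549024752425
15,1.7385965099029934,0.053155347577867364,0.3858465525565008
15,2.1581658991169639,8.4393091414180428e-05,-0.76305720969476754
15,0.5119770730019122,-0.72155803354284742,-1.1124114719834179
15,-0.17293444248330742,0.31649426167330802,1.1911429530888651
15,1.0981321216331437,-0.097286598413489467,0.2627492251471385
15,1.8081938267093323,2.0931683089305948,0.48014340339161082
16,1.4389511720054895,-0.25197737820688537,0.2959939896870995
16,0.98319473714579564,0.15256251210246857,-0.37191458132128985
16,3.0177061058110208,1.471491972993157,-1.7567217824785826
16,-1.6607170789804622,-2.5666584409312976,0.32799548371410964
16,-0.89685443678164323,-0.23685026450968424,1.727350214164185
16,3.5532969684785156,0.17651242137244696,-1.5338614049161376
17,2.9133812839414928,1.7323116054099441,0.066545815859204827
17,4.316884305968494,1.1774118889776937,-0.69742382330027686
17,1.5082440281201746,0.4390866789295762,0.98958393459485305
17,1.5921630511151723,1.7439345261677921,-1.1783036231148656
17,0.8762562777294437,0.43899315873829875,0.78235034241766133
17,0.74410088700046551,0.82798817679705894,-0.19065105750515945
17,-0.25396984871486017,-0.29657095353470836,1.1712470934673194
18,0.85548106824082715,-0.69893042857874632,0.31200947155124387
18,0.3653022598057542,-1.0137173664403989,1.1553120361066962
18,2.5281118368484035,0.032782092876260792,0.60876147222443977
18,0.54403354192179121,-1.2165601493811278,-2.2912895085981
18,0.21235333942501355,-0.67114027739658111,0.3043667290302598
19,-0.4435531832945479,-1.5815943994539423,1.0684715559890383
19,2.2896097659465275,1.4759490480535089,0.23287802013716835
19,2.35102563277768,0.36835661270065839,0.23440089269869593
19,0.50302511319392473,0.846583985843404,0.27034323928172588
19,1.6347391443870434,-0.57094366152179454,-0.86334526473938167
19,3.3609041305103737,0.81376368996621051,-0.14752868024035293
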