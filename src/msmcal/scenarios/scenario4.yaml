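theta:
- 9.0
- -0.3
- -0.1
- 0.5
- 0.5
- 0.5
- 0.5
- 0.1
sigma2_y: 3.0
mu:
- 0.0
- 0.1
- 0.0
- 0.0
- 0.1
omega:
- 2.0
- 0.1
- 0.1
- 0.1
- 0.1
alpha:
- 0.0
- 0.1
- 0.1
- 0.1
- 0.0
- 0.3
- 0.3
- 0.6
- 0.1
n_subjects: 100
n_intervals: 10
irregular_visits: true
unmeasured_confounder: true
seed: 4
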