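# msmcal

Calibrated inverse-probability weights for marginal structural models of
longitudinal outcomes observed at irregular visits, with a
subject-specific latent confounder.

The package provides:

- **`msmcal.dgm`** — a longitudinal panel simulator with Bernoulli
  visit, confounder and treatment processes, treatment–confounder and
  visit–confounder feedback, visit-driven carry-forward of treatment and
  confounder, and outcome masking at non-visits.
- **`msmcal.truth`** — a Monte Carlo G-computation oracle for the true
  marginal effect of the lagged treatment, integrating over the latent
  subject effect, plus the closed-form shortcut for the identity-link
  linear outcome model.
- **`msmcal.propensity`** — pooled logistic numerator/denominator
  models and stabilized cumulative-product treatment/visit weights,
  multi-exposure products, and quantile truncation.
- **`msmcal.calibration`** — exponential-tilting calibration
  `sw * exp(K @ lambda)` under covariate-balance, unity-mean and
  per-subject latent-confounder restrictions, solved by a
  Barzilai–Borwein spectral iteration with a quasi-Newton fallback.
- **`msmcal.gee`** — weighted GEE with identity link, AR(1) or
  independence working correlation, and robust sandwich covariance.
- **`msmcal.experiment`** — the four-scenario Monte Carlo study
  (bias, relative bias, MCE, rMSE, coverage, convergence counts) and an
  application-style multi-exposure pipeline on synthetic data.

## CLI

```sh
# one simulated panel as long-format CSV
msmcal simulate --scenario 4 --seed 1 --out panel.csv

# Monte Carlo study summary for one scenario
msmcal run --scenario 1 --reps 1000 --seed 1 --out summary.csv

# application-style two-exposure pipeline on synthetic data
msmcal app-demo --n 2000 --seed 1
```

Scenario configurations (all data-generating coefficients, panel
dimensions and flags) ship as YAML under `src/msmcal/scenarios/` and can
be overridden with `--config`.

## Conventions worth knowing

- All lagged values are zero before the first interval; the outcome is
  generated only at visit intervals; treatment and confounder carry
  forward deterministically between visits.
- Treatment propensity models are fitted on visit intervals only (where
  treatment is actually drawn); non-visit intervals contribute a weight
  ratio of one. Visit models are fitted on all intervals.
- The marginal outcome model excludes the first interval (simulator
  cold start) — configurable via `burn_in` in `run_replicate`.
- Per-subject latent-balance residuals come from a treatment (or visit)
  model with subject-specific intercepts, so the restrictions are
  attainable near the stabilized weights.
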