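# rollscore

Estimate how a polygenic score's (PGS) effect on a quantitative trait varies
across a continuous moderator (age), using *rolling weights*: one weighted
linear mixed model per integer focus age, with observation weights that are 1
at the focus age and decay with age distance, family random effects, and
family-block bootstrap confidence intervals. An upstream per-wave polytomous
IRT stage (Generalized Partial Credit Model) turns raw ordinal item responses
into relative latent trait scores.

## Components

| module                | purpose                                                                 |
|-----------------------|-------------------------------------------------------------------------|
| `rollscore.kernel`    | three-step age-weight construction (shoulder kernel → min-max → decay)  |
| `rollscore.gpcm`      | GPCM fitting (EM, fixed quadrature) and EAP scoring, one model per wave |
| `rollscore.wlmm`      | weighted linear mixed model with family random intercept (± age slope) |
| `rollscore.rolling`   | standardization, per-age driver, pooled fit, family bootstrap CIs       |
| `rollscore.simulate`  | family-structured longitudinal data with known ground truth             |
| `rollscore.io` / `cli`| CSV/TSV readers and writers, YAML config, command-line entry points     |

The weight at each observation is built in three steps from the focus age
(*center* c), a *shoulder* s (default 1.5) and a *decay* (default 25):

1. `w1 = 1 - |c - age|**s`
2. `w2 = (w1 - min(w1)) / (max(w1) - min(w1))`
3. `w  = w2**decay`

so observations at the focus age weigh exactly 1 and the most distant
observation weighs exactly 0. Weights scale residual precision in the mixed
model (residual covariance `sigma^2 / w`); variance components are estimated
by profiled REML (ML optional). Confidence intervals resample whole families
with replacement (100 replicates per focus age by default), with
`CI = estimate ± 1.96 × bootstrap SE`.

## CLI

```bash
# synthetic dataset with known truth
rollscore simulate --config sim.yaml --seed 3 --out data/

# per-wave GPCM scoring of ordinal item tables
rollscore score-irt --items data/items_wave1.csv --out scores.tsv

# inspect the three weight stages for one focus age
rollscore weights --ages 20,25,30,40 --center 25 --out weights.tsv

# full rolling analysis: pooled fit + one weighted fit per focus age
rollscore run --data data/measures.csv --config run.yaml --out results/

# estimates vs age with the bootstrap CI band
rollscore plot --results results/rolling_results.tsv --out curve.png
```

`run.yaml` keys: `age_min`, `age_max`, `shoulder`, `decay`, `n_boot`, `seed`,
`random_slope`, `method` (reml/ml), `n_jobs`, and `columns` (mapping from
canonical roles — person, family, age, phenotype, pgs, sex, array, pc1..pc5,
wave — to the input file's column names). Outputs: `rolling_results.tsv`
(one row per focus age: estimate, model SE, bootstrap SE, 95% CI, effective N
= sum of weights, significance), `pooled_fit.tsv`, and `run_record.json`
(config echo, seed, versions).

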