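# respondermi

Simulation pipeline for comparing missing-data strategies in **responder
analysis** — trials where a continuous longitudinal outcome is dichotomized
("improved by at least λ") and arms are compared on the difference in
responder proportions.

The package simulates two-arm four-visit trials from a random-intercept
normal model, imposes monotone missing-at-random dropout under six
propensity mechanisms calibrated to a target missingness rate, and handles
the missing endpoints three ways:

* **NRI** — non-response imputation: missing endpoint ⇒ non-responder.
* **IBD MI** — impute the continuous outcomes by FCS (chained equations)
  multiple imputation, then dichotomize each completed dataset.
* **DTI MI** — dichotomize first and multiply impute the binary responder
  indicator directly (logistic conditional model).

Per-imputation estimates of the difference in proportions (Wald) are
combined with Rubin's rules; replicate-level results are summarized as
percent bias, coverage of the 95% CI, power / type-1 error, MCSE, MSE, and
model vs empirical SEs.

## Library quick start

```python
from respondermi import *

data = simulate_trial(PROFILES["linear"], n=200, seed=1)
data = generate_cv(data, profile=PROFILES["linear"], seed=2)
mask = apply_dropout(data, DropoutSpec(model_id=1, target_rate=0.30), seed=3)
masked = mask_dataset(data, mask)

res = run_strategy(masked, "IBD", spec=ImputationModelSpec(M=30), seed=4)
pooled = rubin_pool([(e.diff, e.se) for e in res.per_imputation])
print(pooled.estimate, pooled.ci_low, pooled.ci_high, pooled.p_value)
```

Scenario orchestration (factorial studies, metrics, RNG stream layout)
lives in `respondermi.study`:

```python
cfg = ScenarioConfig(profile="linear",
                     dropout=DropoutSpec(model_id=4, target_rate=0.50),
                     variants=default_variants(4), n_sim=200)
result = run_scenario(cfg, seed=7)
print(result.summary_frame())
```

## CLI

```bash
respondermi simulate --profile linear --n 200 --dropout-model 1 --out trial.csv
respondermi impute --data trial.csv --strategy IBD --m 30 --seed 1
respondermi run-study --profile linear --model 1 --rate 0.3 --n-sim 200 --out results/
respondermi metrics --replicates results/replicates_linear_m1_r30.csv \
    --pi-a 0.259 --pi-b 0.105
```

`run-study` writes `summary.csv` (table-shaped metrics per scenario ×
method), per-scenario replicate CSVs, and `metrics.json`. A single scenario
can also be specified as YAML (`--config scenario.yaml`; see
`respondermi.study.load_config`).

## Layout

| module | contents |
| --- | --- |
| `respondermi.trial` | profiles, trial simulator, CV/AE generators, responder rule, analytic rate oracle |
| `respondermi.dropout` | six dropout propensity models, cutoff calibration, mask application |
| `respondermi.impute` | NRI, FCS engine (Bayesian linear + logistic draws), strategy runner |
| `respondermi.pooling` | difference-in-proportions estimate, Rubin's rules |
| `respondermi.metrics` | percent bias, replicate sizing, scenario summaries |
| `respondermi.study` | scenario/study orchestration, seeds, CSV/JSON outputs |
| `respondermi.cli` | `respondermi` command group |
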