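# fusesurv

Multimodal late-fusion survival modelling for oncology-style cohorts:

- **Synthetic cohorts** (`fusesurv.synthetic`) — seeded generator emulating a
  lung-cancer cohort: demographics, ordinal staging, 107 radiomic features in
  7 block-correlated families, Weibull proportional-hazards outcomes and
  calibrated independent exponential censoring.
- **Cox engine** (`fusesurv.cox`) — Breslow-ties partial likelihood with
  analytic gradient/Hessian, Newton fitting with step-halving, Breslow
  baseline cumulative hazard, linear-predictor risk scores and landmark
  absolute risk `1 − S(t*|x)` (default horizon 1.5 years).
- **Group lasso** (`fusesurv.grouplasso`) — group-lasso penalized Cox
  (ℓ2 within family, ℓ1 across families, weights `w_g = √p_g`), proximal
  gradient solver with active-group working sets and Newton polish,
  warm-started regularisation paths, Verweij–van Houwelingen cross-validated
  deviance for penalty selection, selection-frequency reporting.
- **Fusion** (`fusesurv.fusion`) — stratified outer folds, leakage-free
  out-of-fold modality risk scores (clinical / demographic / radiomic), and
  five meta-learners: Cox fusion, equal/optimised weighted averaging,
  landmark logistic stacking with elastic-net mixing, a random survival
  forest and a gradient-boosted-tree stack (both external learners behind a
  fit/predict contract).
- **Stratification** (`fusesurv.stratify`) — outcome-guided two-cutoff
  search maximising the K-sample log-rank statistic over a central quantile
  grid under minimum-group-size (and soft monotone event-rate) constraints;
  fold-averaged cutoffs; group summaries with Kaplan–Meier medians.
- **Metrics** (`fusesurv.metrics`) — from-scratch Harrell C-index,
  cumulative/dynamic time-dependent AUC with IPCW, Brier and integrated
  Brier score, Kaplan–Meier, calibration slope/intercept, bootstrap CIs.
- **Pipeline + CLI** (`fusesurv.pipeline`, `fusesurv.cli`) — end-to-end
  driver exporting tidy CSV reports (model performance, selection
  frequency, EPV, risk-group distributions, KM curves, calibration,
  hazard ratios, stage-by-risk-group flows).

## CLI

```bash
fusesurv simulate --seed 1 --out sim/                 # cohort.csv + taxonomy
fusesurv fit-signature --cohort sim/cohort.csv \
    --taxonomy sim/cohort_taxonomy.csv --seed 1 --out sig/
fusesurv run-all --seed 1 --out report/               # full pipeline on a
                                                      # default synthetic cohort
fusesurv run-all --cohort my.csv --taxonomy tax.csv --seed 1 --out report/
fusesurv stratify --risks risks.csv --out strat/
fusesurv evaluate --risks risks.csv --out eval/
```

`run-all` accepts `--config cfg.yaml` with `simulate:` (cohort spec fields)
and `fusion:` (meta-learner grids) sections plus any `RunConfig` field, and
`--seed/--horizon/--folds` overrides. Exit codes: 0 success, 1 validation
error, 2 runtime failure.

Cohort CSVs need columns
`id,time_years,event,age,gender,overall_stage,t_stage,n_stage` followed by
feature columns; the taxonomy CSV maps `feature,family`.

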