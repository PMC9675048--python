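# nrquant

Nonresponse-adjusted estimation of post-discharge opioid consumption
quantiles from survey data linked to EHR covariates.

Patient-reported opioid consumption surveys suffer informative
nonresponse: the patients who answer differ systematically from those who
don't, on characteristics that also drive consumption. `nrquant`
implements an end-to-end pipeline that measures and corrects this bias:

- **`nrquant.synthcohort`** — synthetic surgical cohorts with calibrated
  marginals (~29% zero-prescription patients, ~20% survey response),
  a logistic response model in covariates, consumption bounded by
  prescription size, configurable covariate missingness, and large-sample
  ground-truth quantile oracles.
- **`nrquant.cohort`** — eligibility filtering, pill-to-MME conversion
  (CDC equianalgesic factors), the known-zero rule (no prescription ⇒
  measured zero consumption), and design-matrix construction.
- **`nrquant.missing`** — generalized low-rank model imputation
  (alternating ridge least squares over observed cells) plus
  missingness-indicator predictors with perfect-collinearity pruning.
- **`nrquant.bivariate`** — nonresponse diagnostics: covariate binning,
  chi-squared tests (Yates on 2×2), two-sample Kolmogorov–Smirnov,
  monthly rate series.
- **`nrquant.stack`** — cross-validated convex stacking ("super learner")
  over a library of mean / MME-stratified / OLS / lasso / random-forest
  learners (plus sum-of-trees for the binary propensity task), each
  optionally screened to predictors correlated with the target at p<0.1.
- **`nrquant.drquantile`** — the double-robust targeted estimator:
  ensemble propensity scores for measurement, per-threshold CDF
  regressions, a per-threshold logistic fluctuation solving the
  influence-curve score equation, isotonic monotonization, quantile
  inversion, and influence-curve confidence bands.
- **`nrquant.treeimp`** — variable importance by tree-split counts with
  random-forest pre-screening of whole variables.
- **`nrquant.report`** — adjusted-vs-unadjusted correction summaries,
  reference-survey comparison, prescription-vs-consumption gaps, rolling
  quantile trends, and a reproducible report bundle.
- **`nrquant.sumtrees`** — a compact Bayesian sum-of-trees sampler
  (backfitting MCMC, grow/prune proposals, probit augmentation) used as a
  library member and importance tally engine.
- **`nrquant.validation`** — Monte-Carlo studies: double-robustness bias,
  CI coverage, null calibration, planted-signal importance.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` runs the Monte-Carlo acceptance criteria
(double robustness at n=20,000 × 50 replicates, 95% CI coverage over 200
replicates, etc.) and takes several minutes; the remaining suite is fast.

## CLI

```bash
nrquant --seed 1 --outdir out all          # full pipeline on a synthetic cohort
nrquant --seed 1 --outdir out simulate     # or stage by stage:
nrquant --seed 1 --outdir out assemble
nrquant --seed 1 --outdir out impute
nrquant --seed 1 --outdir out diagnose
nrquant --seed 1 --outdir out estimate
nrquant --seed 1 --outdir out importance
nrquant --seed 1 --outdir out report
```

Options: `--config cfg.yaml` (keys like `n_patients`, `levels`, `folds`,
`min_group_n`, `grid_max_points`, `truncation_bounds`, `population`
(`prescribed`|`all`), `glrm_rank`, `eligibility_rules`), `--seed` (single
root seed; all randomness derives from it via counter-based sub-streams),
`--outdir`. Every artifact is listed in `run_manifest.json` with its
producing stage and seed. Logs go to stderr and `<outdir>/run.log`.

## Cohort table schema

`synthcohort.generate_cohort` / the CLI `simulate` stage write a
comma-separated table with one row per patient:

| column | meaning |
| --- | --- |
| `patient_id` | integer id |
| `procedure_group` | surgical procedure label |
| `discharge_month` | ISO `YYYY-MM` |
| `age_years`, `sex`, `race`, `tobacco_use`, `alcohol_use`, `asa_class`, `los_category`, `preop_assessment` | EHR covariates |
| `opioid_drugs_prescribed` | 0–3 |
| `prescribed_mme`, `discharge_day_mme` | morphine milligram equivalents |
| `responded` | survey response flag |
| `measured` | consumption measured (response or EHR-documented zero prescription) |
| `consumed_mme` | reported consumption, absent when unmeasured |
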