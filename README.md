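# gistnomo

Survival nomogram pipeline for gastric gastrointestinal stromal tumor
(GIST) registry cohorts: categorical missing-data imputation, balance-gated
repeated train/test splitting, five Cox proportional-hazards model
families, time-dependent AUC comparison at six horizons, and nomogram
point-table export.

The package is aimed at biostatisticians building prognostic nomograms
from SEER-style registry exports — patient tables dominated by
multi-category variables (race, tumor size class, AJCC stage, mitotic
rate, surgery type, ...) with missing cells, a numeric age, survival
months, and overall-survival (OS) / cancer-specific-survival (CSS) event
flags. Because registry microdata are access-restricted, the package ships
a synthetic cohort generator that reproduces the structure of such an
export (category marginals, a Gaussian-copula dependence among the
severity variables, competing-cause exponential event times with known
log-hazards), so every stage is testable end to end with ground truth in
hand.

## What it computes

**Imputation.** Missing cells of multi-category variables are filled by an
iterative boosted-tree ensemble: variables are visited in ascending order
of missing count; each is re-imputed by a gradient-boosted decision-tree
learner (native categorical handling; LightGBM binding) trained on the
currently completed table; passes repeat until a missForest-style
divergence rule fires; m independent chains are aggregated per cell by
majority vote. Accuracy is scored as PFC (proportion of falsely
classified masked cells) and NRMSE for numeric columns.

**Splitting.** Candidate 7:3 splits are drawn by simple random sampling
and accepted only when every covariate passes a balance test
(per-level 2×2 chi-squared with continuity correction; Kolmogorov–Smirnov
for age), repeated until the requested number of gated splits is reached.

**Models.** Five Cox constructors over the dummy-encoded design
(reference level dropped for unpenalized fits, full one-hot for penalized
ones; age stays numeric):

* `two_stage` — univariate screen at p < 0.05, multivariate retention at
  p < 0.05, final refit (Breslow ties, Wald CIs);
* `lasso`, `ridge`, `enet` — elastic-net-penalized partial likelihood
  (γ = 1, 0, 0.5) with λ chosen by 5-fold cross-validated deviance;
* `cox_with_lasso` — unpenalized refit on the lasso's nonzero set.

**Evaluation.** IPCW cumulative/dynamic AUC at 6, 12, 36, 60, 84 and 120
months, for every (model, split) pair, summarized as mean AUC,
interquartile range, and top-1 / top-3 rank counts per horizon.

**Nomogram.** Any unpenalized fit converts to the classical 0–100 point
scale (largest |β|·range spans 100 points) with tabulated
total-points→survival maps per horizon, exported as JSON.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
5463-patient cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort + missingness
python analysis/02_impute_missing.py       # fill gaps, score PFC
python analysis/03_descriptives_and_splits.py
python analysis/04_fit_models.py           # the five model families
python analysis/05_horizon_auc.py          # 5 models x 10 splits x 6 horizons
python analysis/06_build_nomogram.py       # point-table export
```

Representative output (seed defaults):

```
cohort: 5463 patients, OS deaths 33.3%, CSS deaths 25.5%
  Tumor_grade              PFC 0.251 (mode baseline 0.266)
age: median 64 [54, 74]
strongest categorical association: Tumor_size vs AJCC_stage (|Phi| = 0.55)
10 balanced splits accepted in 40 attempts; sizes 3824 train / 1639 test
[OS] two-stage kept 11 features: age_years, Sex_Male, Race_Black, ...
[OS] lasso-Cox: lambda* = 0.000066, 19 nonzero of 31
[OS] ridge-Cox: lambda* = 0.015118, 31 nonzero of 31
most often best by mean AUC: two_stage
[OS] nomogram -> nomogram_os.json; round-trip max error 8.43e-06
```

Reading the numbers: the two-stage screen retains 11 of 20 candidate
dummies (e.g. `Surgery_No surgery` HR 4.01, 95% CI 3.52–4.56 — patients
not operated on die at four times the rate of locally excised ones), the
penalized one-stage models keep more features (lasso 19, ridge all 31),
and across the gated splits the two-stage model attains the best mean
time-dependent AUC at most horizons — the parsimonious classical recipe
wins on this data-generating process, with the lasso-refit hybrid close
behind. The imputer beats unconditional mode filling exactly where the
cohort carries an exploitable association (grade, mitotic rate, size) and
matches it where covariates are independent.

A `gistnomo` CLI wraps the same stages (`simulate`, `impute`, `splits`,
`fit`, `evaluate`, `nomogram`); every subcommand takes `--seed` and writes
a run manifest next to its output.

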