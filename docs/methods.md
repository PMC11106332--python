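# Methods

## The estimation problem

Registry cohorts of gastric GIST patients are dominated by
multi-category covariates, carry missing cells on several of them, and
record two right-censored outcomes: overall survival (OS, death from any
cause) and cancer-specific survival (CSS, death from the tumor; other
deaths censored). The pipeline builds prognostic Cox nomograms under five
construction recipes and asks which discriminates best, at which horizon,
once the randomness of the train/test split itself is averaged out.

## Synthetic cohort generator

The generator emulates a SEER-style export at the granularity of a
published demographics table.

* **Covariates.** Eleven categorical variables with fixed level sets; the
  default marginals are shipped as whole-population counts
  (`data/table1_marginals.yaml`, n = 5463) and converted to probabilities
  as count/total. Age is a truncated normal on [20, 95] with mu = 64.3,
  sd = 14.4, chosen once so the median is 64 and the interquartile width
  19 (the printed quartiles 54/73 are matched to within 0.5 years; three
  quantiles over-determine a two-parameter family).
* **Dependence.** The ordered severity variables (tumor size, AJCC stage,
  grade, mitotic rate) are drawn through a Gaussian copula (rank
  correlation 0.6 within the size–stage and grade–mitotic pairs, 0.25
  across) via the inverse CDF of each marginal, which preserves marginals
  exactly while reproducing the strong grade–mitotic / size–stage
  association pattern real cohorts show on a Phi heatmap. All other
  covariates are independent — a deliberate simplification.
* **Outcomes.** Two competing exponential causes: cancer death with
  hazard h0·exp(x·β_cancer) and other-cause death with hazard
  ρ·exp(x·β_other); independent exponential censoring and an
  administrative follow-up cap (250 months). `os_event` fires when either
  death precedes censoring; `css_event` additionally requires the cancer
  cause to arrive first, so css ≤ os by construction and treating
  other-cause deaths as censoring in the CSS analysis is exactly right
  for this law. The exponential choice buys closed-form checks: with no
  competing cause the Cox estimand equals β_cancer exactly, which the
  parameter-recovery tests exploit.
* **Defaults.** β_cancer mirrors the effect sizes reported for gastric
  GIST cancer-specific survival (age 1.03/yr, male 1.6, black race 1.7,
  unmarried 1.4, poor grade 1.6, 5–10 cm 2.5, ≥10 cm 2.8, stage III 2.5 /
  IV 2.2, no surgery 4.9, >4 nodes examined 1.6, as hazard ratios);
  β_other is an age effect of 0.09/yr approximating background mortality.
  Baseline rates (cancer 4e-4, other 5e-4, censoring 6e-3 per month) are
  calibrated so a 5463-patient cohort shows ≈33% overall deaths, ≈25%
  cancer deaths and ≈70 months median follow-up — registry-like for a
  2000–2020 accrual window.
* **Missingness.** MCAR blanks cells independently; MAR shifts the
  blanking log-odds by log(OR) for rows in a driver level, with the base
  rate solved (Brent) so the overall fraction still hits the target. The
  driver must be fully observed.

What passing tests on this generator do **not** show: robustness to
non-proportional hazards, informative censoring, reporting-delay or
recode artifacts, MNAR missingness, or covariate dependence beyond the
four linked severity variables.

## Imputation algorithm

For a table with missing categorical (and optionally numeric) cells:

1. order variables ascending by missing count (ties keep column order);
2. initial fill: column mode (categorical) or mean (numeric);
3. per pass, re-fit a gradient-boosted decision-tree learner for each
   incomplete variable on its observed rows (all other, currently
   completed, columns as predictors) and re-predict its masked cells;
4. stop when the change statistic — fraction of imputed categorical cells
   that changed plus normalized squared numeric change — first rises
   (returning the previous iterate) or falls below `tolerance` (1e-4), or
   after `max_passes` (10);
5. run m = 5 such chains from seeds spawned off the master seed and
   aggregate per cell: majority vote (ties to the lowest-index chain,
   recorded in the aggregation record) or mean.

The learner is a pluggable `fit`/`predict` interface; the reference
binding is LightGBM with 200 trees, depth 6, learning rate 0.1, and
row/column bagging (0.9/0.9 per iteration). Bagging matters: without it
the learner is deterministic and all chains coincide, collapsing the
ensemble. Observed cells are never altered; imputed categorical values
are restricted to levels observed in that column by construction.

Benchmarks use PFC (masked categorical error rate) and NRMSE (masked
numeric RMSE over the truth column SD). Mode/mean filling is the
baseline comparator; on tables with exploitable inter-variable signal the
ensemble's mean PFC is strictly lower, and on a variable that is a
deterministic function of an observed one it attains zero error. Where a
variable is independent of all predictors, unconditional mode filling is
already Bayes-optimal and the ensemble can only match it — visible in
the worked example for marital status and tumor location.

## Preparation

The exclusion cascade applies eight registry criteria (non-stomach site,
age < 20, unknown race, not first malignant, unknown/zero size, no or
unknown surgery status, unknown death cause, survival < 3 months) in
order, attributing each removed row to the first criterion it fails;
criteria whose column is absent pass vacuously, since synthetic cohorts
are born pre-coded. Numeric recoding uses half-open (lo, hi] bins —
size (0,2], (2,5], (5,10], (10,∞) cm; mitotic ≤5 vs >5 per 5 HPF; nodes
0, 1–4, >4 — so printed ≤/≥ endpoints land in the closed side. The
65-year age split exists only for Kaplan–Meier display; models always
take age numerically.

Dummy encoding has two modes: reference-dropped (20 columns inc. age;
references: Female, White, Married, Antrum or Pylorus, well/moderately
differentiated, ≤2 cm, stage I, ≤5/5 HPF, local excision, 0 nodes,
no/unknown chemotherapy) for unpenalized fits, and full one-hot
(31 columns) for penalized fits, where the penalty restores
identifiability and no level is privileged. Association between
categorical pairs uses the Phi coefficient: the signed 2×2 formula for
binary pairs, √(χ²/n) otherwise.

## Splitting protocol

Candidate 7:3 partitions (|train| = round(0.7·n)) are simple random
draws; a draw is accepted only if every covariate passes its balance
test at α = 0.05: each categorical *level* via a 2×2 chi-squared of
level-membership × cohort with Yates continuity correction, age via a
two-sample Kolmogorov–Smirnov test (a Kruskal–Wallis rank test is
selectable — both conventions appear in the literature for this exact
comparison). The continuity-corrected variant was pinned because it
reproduces the published per-level p-values (0.817 on the ≤2 cm cell,
0.210 on the Body cell) where the uncorrected one does not. Rejection
sampling is capped at 10,000 attempts; the error names the most
frequently failing variable. Yates correction makes the gate mildly
conservative (per-level rejection ≈3–5% at α = 5%), which only makes
accepted splits more balanced.

## Cox model families

All unpenalized fits maximize the Breslow-tie partial likelihood. A
statsmodels PHReg fit provides starting values; a guarded Newton
iteration on the exact Breslow objective polishes them until the score
equation holds to < 1e-6, and Wald CIs/p-values come from the observed
information at the optimum. The Breslow estimator supplies the baseline
cumulative hazard on the event-time grid; predictions use
S(t|x) = S0(t)^exp(x·β), with horizons beyond the grid clamped to the
last point under a warning.

Two-stage selection operates at dummy granularity: stage 1 fits one Cox
model per source variable (age alone; a categorical variable with all
its non-reference dummies) and advances dummies with p < α; stage 2 fits
the joint model and retains dummies with p < α; the final model is refit
on the retained set and the full trace is stored. Individual dummies,
not whole variables, pass the gate — a variable can keep one level and
lose another.

Penalized fits minimize −loglik/n + λ(γ‖β‖₁ + (1−γ)‖β‖²/2). Lasso
(γ=1) and elastic net (γ=0.5) use scikit-survival's Coxnet path solver
over 100 log-spaced λ (path floor 1e-4·λ_max); ridge (γ=0) is outside
Coxnet's domain and is fit by the package's own Newton solver on the
ridge-penalized objective over a 30-point grid anchored two decades above
the lasso λ_max (ridge needs heavier λ to shrink visibly). Features are
standardized internally and coefficients reported on the original scale.
λ is chosen to minimize the 5-fold mean test-fold deviance
−2·loglik(β̂_train; fold), with fold assignment random given the seed
(only the outer 7:3 split is balance-gated). `cox_with_lasso` refits the
lasso's nonzero set unpenalized after mapping it to an identifiable
basis: if every level of a variable was selected, its reference level is
dropped.

## Time-dependent evaluation

Discrimination at horizon t uses the IPCW (Uno-type) cumulative/dynamic
AUC: cases are subjects with events by t (weight 1/Ĝ(T⁻)), controls are
subjects at risk beyond t (weight 1/Ĝ(t)), with Ĝ the Kaplan–Meier
estimate of the censoring distribution and tied scores counting ½. The
estimator agrees with brute-force weighted pair enumeration to machine
precision and with scikit-survival's implementation on tie-free data.
Horizons are fixed at 6, 12, 36, 60, 84, 120 months (near-, mid-,
long-term pairs). Per split, every model is re-fit on the train cohort —
including its internal selection and cross-validation — and scored on
the test cohort; a failing (model, split) cell is logged, recorded as
NaN, and excluded from that split's ranking rather than imputed. Ranking
ties all receive the better rank (ties are logged; top-1 conservation is
asserted only in the no-tie regime).

## Nomogram construction

The classical linear point scale: points(f, v) = 100·β_f(v − anchor_f) /
max_g|β_g|·range_g, anchored so all points are non-negative (negative
effects anchor at their high end); binary dummies range over {0, 1},
age over a configurable anchor range (default: observed min/max).
Total points map to survival per horizon through the model's own
baseline on a 500-node grid with linear interpolation; the grid is fine
enough that read-off survival agrees with the model to < 1e-4, well
inside the 0.005 design bound. Penalized fits are rejected — their
coefficient basis is over-complete — with a pointer to the
lasso-selected refit.

## Problem sizes

The shipped analysis and the acceptance script run at desk scale, chosen
as the package's own defaults: a 5463-patient cohort with 10 gated
splits for the worked example; 120 replicate cohorts (n = 3000) for CI
coverage; 40 replicates for selection power; 20–50 replicates (n =
1000–2000) for the imputation benchmarks; a 1200-patient, 5-split,
five-model grid for the comparison summary. The test suite asserts the
same properties at the sizes documented in each test.

## Known limitations

* The imputer's stopping statistic and aggregation operator are one
  principled reading of the multiple-imputation lineage (missForest-style
  divergence; majority vote); other conventions exist.
* No Rubin's-rules variance pooling: the ensemble yields a single
  completed table, so downstream standard errors ignore imputation
  uncertainty.
* No proportional-hazards diagnostics, no Efron/exact ties, no Fine–Gray
  competing-risk model for CSS, and no calibration/decision-curve
  evaluation — discrimination only.
* The generator's OS coefficients are implied by the two cause-specific
  sets rather than freely specifiable; with a nonzero other-cause rate
  the OS hazard is only approximately proportional.
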