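# Methods

This note documents the models and procedures implemented in `rfclust`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Cohort model and coding

A cohort is one row per participant with the five risk factors — sex
(male = 0, female = 1), age (years), BMI (kg/m²), hypertension (HTN,
0/1) and family history of diabetes (FHDM, 0/1) — and the type 2
diabetes outcome `dm` (0/1).  Validation removes rows missing any of
these six columns, applies an age window (default 40–70 years, the
range of the source cohorts), and, when an age-at-diagnosis column is
present, excludes participants diagnosed before age 20 (a guard against
type 1 diabetes).  Optional columns: monthly-rounded follow-up time and
event flag, fasting glucose (FG), total cholesterol, triglycerides, HDL
(mmol/L), and a prior-diagnosis flag.  Diabetes and hypertension can be
derived from raw measurements (FG ≥ 7.0 mmol/L, 2-h OGTT ≥ 11.1 mmol/L,
HbA1c ≥ 6.5%, prior history; BP ≥ 140/90 mmHg or medication), with
glucose units declared explicitly — never auto-detected.

## Gower dissimilarity

Numeric variables contribute `|a−b| / range`, with ranges taken from
the clustering data unless overridden; resolved ranges are stored on
the distance matrix so a second cohort can be scored on the discovery
scaling.  Binary risk factors are asymmetric: joint absence is excluded
from the weighted average, so sharing a *present* risk factor pulls
participants together while sharing its absence is uninformative.

Sex is treated as an asymmetric binary by default.  This follows the
literal description of the original analysis (all binaries asymmetric,
male coded 0), and means male–male pairs have no sex term in the
denominator.  A symmetric alternative is available
(`default_variable_specs(sex_asymmetric=False)`); in our synthetic
experiments the asymmetric default recovers planted structure markedly
better, so the switch exists for sensitivity analysis only.

Degenerate cases: a constant numeric variable contributes 0 and is
flagged; a pair whose every variable is an absent asymmetric binary has
an empty denominator and returns distance 0 with a warning (impossible
once age/BMI are included).  Distances are float64, stored condensed,
and validated against the R `cluster::daisy` reference on a frozen
fixture (agreement to 1e-12; see `tests/data/`).

## Clustering and cluster-count selection

Complete-linkage agglomerative clustering (scipy's nearest-neighbour
chain; deterministic, with equal-height ties resolved by node index)
produces the merge tree; cutting at k undoes the last k−1 merges.

The cluster count is chosen by outcome heterogeneity: for each k in
[k_min, k_max] (defaults 2 and 12 — the scan bounds are not dictated by
the method and are configurable), the 2×k non-diabetic/diabetic table
is tested with a Pearson chi-square without continuity correction,
df = k−1.  P-values are computed and compared in natural-log space; for
statistics beyond scipy's `chi2.logsf` underflow (~stat > 1.4e3) the
asymptotic expansion of the upper incomplete gamma function takes over,
so heterogeneity in the p ≈ 1e-3000 regime still orders correctly.

Two selection policies are provided:

* **global** (default): clusters are split until prevalence
  heterogeneity is maximal — the k with the smallest log p over the
  scan, ties to the smaller k.
* **local**: the first k whose test is strictly more significant than
  at k+1; ties continue the scan; an exhausted scan returns k_max.

The two coincide whenever significance increases monotonically up to
the optimum, which is the regime described for the source analysis.  On
synthetic cohorts, however, an early tree cut is occasionally
prevalence-neutral (the statistic barely moves while df rises), which
stalls the local rule far below the heterogeneity optimum; the global
policy is therefore the default.  Cuts producing a cluster below a
configurable size floor, or an inestimable test (zero expected count),
enter the trace as log p = +inf and can never be selected.

Clusters are finally renumbered CL1..CLk by ascending unrounded
prevalence; ties break by descending cluster size, then original label.

## Synthetic cohorts

The generator emulates the published per-cluster composition of the
discovery cohort (six clusters, n = 10,023) and of the pooled
cross-sectional validation cohorts (n = 215,083): cluster sizes, exact
male/female counts, age and BMI means/SDs, fixed HTN/FHDM flags, and
per-cluster diabetes prevalence.  Specifics:

* Age and BMI are truncated normals (age to the 40–70 window, BMI to
  15–50 kg/m²).  The latent location is solved so the *post-truncation*
  mean equals the published mean, since the published moments describe
  observed (already range-restricted) data.
* Sex counts are exact; HTN/FHDM are constant within a cluster (an
  optional noise rate can flip them, mimicking the small impurity the
  validation cohort shows in cluster 5).
* `dm` is Bernoulli(prevalence); a hidden `true_cluster` column
  supports recovery testing.
* Follow-up: exponential time to incident diabetes with a
  cluster-specific hazard, independent exponential censoring (default
  0.003/person-month, a free parameter — the source reports only
  person-years and mean visits), truncation at 120 months, times
  rounded up to whole months to match monthly visit recoding.  Default
  hazards scale an overall 0.0021/person-month rate (≈18% conversion
  over ten years, matching the reported 1,384 incident cases among
  7,574 at risk) by each cluster's relative prevalence, which
  reproduces the reported ordering of cumulative incidence.
* Biomarkers are normal per (cluster, diabetes-status) cell in mmol/L.
  Default means give FG a strong status effect, a mild cluster-level
  shift proportional to relative prevalence, and a planted 0.4 mmol/L
  non-additive bump in the diabetic cells of two clusters, so the
  cluster × status interaction that the source reports for FG is
  present and recoverable by the ANOVA at the default sample sizes.

What the synthetic cohorts do **not** model: real covariance between
age, BMI and the categorical factors within clusters; non-normal or
multimodal age structure; informative censoring; visit-schedule
artefacts; measurement error.  Consequently, passing the recovery tests
shows the pipeline correctly identifies structure of the kind the
published composition describes — it does not show the six published
clusters would re-emerge from any particular real population.  In
particular, clusters distinguished only by a numeric variable (the two
all-male, no-HTN/no-FHDM clusters differ mainly by age, means 45.7 vs
61.9) are genuinely hard for complete linkage when ages are drawn from
overlapping truncated normals: across generator seeds the scan
typically selects 6 clusters (the modal outcome at the 3,000-row
subsample used in tests) but can return 7–9 when the male age continuum
fragments into three bands before the hypertensive branch splits.  This
instability is a property of the idealised age model, not of the
selection rule; the adjusted Rand index against planted clusters
exceeds 0.95 whenever k = 6 is selected.

## Label transfer

The cluster classifier is an RBF-kernel SVM (one-vs-one multiclass)
on z-scored features, grid-searched over the margin penalty C ∈ {1, 10,
100} and kernel width γ ∈ {scale, 0.1, 1} with stratified 5-fold CV,
inverse-frequency class weights (the smallest published cluster holds
277 of 10,023 participants), and a fixed seed.  The detailed original
tuning procedure is not public, so every choice is exposed in
configuration rather than asserted as canonical; a multinomial-logistic
fallback aids debugging.  The scaler is frozen at training: assigning a
validation cohort never refits it (tested by showing predictions track
a global feature shift instead of being invariant to it), and
predictions only ever use labels seen in training.

## Survival and biomarker validation

Kaplan–Meier disease-free curves and the k-sample log-rank test
(lifelines) operate on baseline non-diabetic rows with monthly-rounded
times; simultaneous events at a month use the standard tied-death
convention.  Cumulative incidence is deliberately the simple
events/initial-at-risk proportion (matching the definition used with
the source figure), not 1 − KM.

Two-way ANOVA (statsmodels OLS) fits
`biomarker ~ cluster * status`; unbalanced designs default to Type II
sums of squares — the conventional choice when the interaction is
itself under test, and the interaction term is identical across types
(asserted in tests).  Effect dfs are (k−1), 1, (k−1); empty cells make
the interaction inestimable and raise.  Restricting to never-diagnosed
participants (via `prior_dx`) isolates natural biochemical differences
from treatment effects.

## Prediction performance

Per-cluster risk scores are logistic regressions of `dm` on the five
risk factors (the standard risk-model family; the original modelling
details are not public).  Within-cluster constant predictors are
dropped automatically; separation or non-convergence falls back to a
penalised fit with a warning.  Evaluation is apparent (in-sample) AUC
by default — a cross-validated variant would also be reasonable, but
the choice only matters for absolute levels, not the between-cluster
contrasts the analysis is about.

AUC is the Mann–Whitney statistic with ties counted 1/2, exactly equal
to exhaustive pair counting (tested to 1e-12).  Uncertainty uses
DeLong's structural components: the variance of per-case and
per-control placement values.  Confidence intervals and the
between-cluster z-test share this variance, keeping interval and test
coherent.  Clusters are disjoint participant sets, so comparisons are
unpaired (variances summed); the paired variant (shared subjects)
subtracts twice the placement covariance.  Null calibration of the
unpaired test is verified by simulation (rejection rate 0.05 ± 0.01
over 2,000 replicates).

Fasting-glucose threshold sweeps report, per cluster and threshold t,
sensitivity P(FG ≥ t | dm = 1) and specificity P(FG < t | dm = 0) as
exact finite-sample proportions over a default grid of 4.95–5.5 mmol/L
in 0.05 steps; a cluster missing an outcome class yields flagged NaN
entries rather than fabricated values.

## Numerical and reproducibility notes

* All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived streams (follow-up, biomarkers,
  subsampling) use `SeedSequence` spawns so adding one stage never
  perturbs another.
* The O(n²) distance matrix is the pipeline bottleneck (~40 s and
  ~2 GB at n = 10,023 on one core); tests and the analysis script use a
  proportional stratified 3,000-row subsample (~2 s), which preserves
  cluster composition to within one row per stratum.
* Chi-square comparisons never leave log space; survival times are
  validated as whole months; distances are clipped to [0, 1] against
  float round-off.

## Known limitations

* The heterogeneity scan tests nested cuts of one tree; it is not a
  general model-selection criterion and inherits complete linkage's
  sensitivity to outliers.
* The exponential follow-up model has constant hazards; it cannot
  express the late-follow-up curvature real cohorts show.
* Between-cluster AUC comparisons assume independent samples; applying
  the unpaired test to overlapping populations would understate the
  variance of the difference.
* The published real-cohort AUC levels (0.58–0.89) are not reproducible
  without the restricted data and serve only as qualitative ordering
  references for synthetic analogues.
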