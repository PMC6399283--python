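# rfclust

Risk-factor-based clustering (RFC) of epidemiological cohorts for type 2
diabetes susceptibility stratification.

Type 2 diabetes develops heterogeneously: subpopulations with different
combinations of risk factors carry very different disease burdens.  This
package identifies such subpopulations directly from five routinely
collected risk factors — sex, age, body-mass index (BMI), hypertension
(HTN) and family history of diabetes (FHDM) — and characterises how
diabetes prevalence, incidence, biochemistry and prediction performance
differ between them.  It is aimed at biostatisticians and epidemiologists
working with cohort data (one row per participant, CSV/TSV).

## Method

1. **Mixed-data dissimilarity.**  Participants are compared with the
   Gower distance
   `d(a,b) = Σ_v w_v δ_v d_v(a,b) / Σ_v w_v δ_v`,
   where numeric variables (age, BMI) contribute `|a_v − b_v| / range_v`
   and binary risk factors are *asymmetric*: a shared absence (0–0)
   carries no information and is excluded from the average (δ_v = 0).
2. **Agglomerative clustering.**  Complete-linkage hierarchical
   clustering of the distance matrix; cutting the tree at k undoes the
   last k−1 merges.
3. **Outcome-driven cluster count.**  For each k in a scan range, the
   2×k table of non-diabetic/diabetic counts per cluster is tested with
   a Pearson chi-square (df = k−1, p-values kept in log space).  The
   scan keeps splitting until the prevalence heterogeneity is maximal
   (most significant); a strictly local first-improvement stopping rule
   is available as an option.  Clusters are labelled CL1..CLk by
   ascending diabetes prevalence.
4. **Label transfer.**  An RBF-kernel SVM (features z-scored on the
   training cohort only, hyperparameters by stratified CV) maps the five
   risk factors to cluster labels so independent cohorts can be assigned
   without re-clustering.
5. **Cluster validation.**  Kaplan–Meier disease-free curves and the
   k-sample log-rank test on follow-up data; two-way
   (cluster × diabetes status) ANOVA with interaction for fasting
   glucose, total cholesterol, triglycerides and HDL; per-cluster
   logistic risk scores with ROC/AUC, DeLong confidence intervals and
   between-cluster AUC comparisons; fasting-glucose threshold sweeps
   (default 4.95–5.5 mmol/L).

Because the source cohorts are access-restricted, the package ships a
synthetic-cohort generator parameterised by the published per-cluster
composition (sizes, sex mix, age/BMI moments, HTN/FHDM flags,
prevalences), plus exponential incident-diabetes follow-up and normal
per-(cluster, status) biomarkers.  Every pipeline stage is testable
against it.

## Worked example

```python
import rfclust as rc

cfg = rc.SimulationConfig(specs=rc.default_discovery_spec(), seed=1)
cohort = rc.generate_cohort(cfg)                    # 10,023 participants
sub = rc.stratified_subsample(cohort, 3000, seed=1) # keep O(n^2) tractable
res = rc.RiskFactorClustering(sub).fit()
print(res)
```

```
Risk-factor-based clustering
  n = 3000, selected k = 6 (heterogeneity maximal at k=6 over scan [2, 12])
  heterogeneity chi-square = 148.95, df = 5, log10 p = -29.65
cluster   n  n_male  n_female  age_mean  age_sd  bmi_mean  bmi_sd  htn_frac  fhdm_frac  prevalence
    CL1 970       0       970     51.10    6.74     24.23    3.29      0.00       0.00        0.10
    CL2 647     647         0     46.53    4.68     24.47    2.70      0.00       0.00        0.11
    CL3 250     250         0     63.43    3.19     22.51    2.80      0.00       0.00        0.20
    CL4 258     118       140     47.69    4.94     24.32    3.02      0.00       1.00        0.22
    CL5 792     360       432     56.32    7.42     25.72    3.21      1.00       0.00        0.25
    CL6  83      37        46     53.20    6.85     26.63    3.42      1.00       1.00        0.47
```

The fit finds six clusters whose diabetes prevalence spans 0.10 to 0.47.
Each cluster is a distinct risk-factor profile: e.g. CL1/CL2 are
younger participants without hypertension or family history (lowest
prevalence), while CL6 combines hypertension, family history and the
highest BMI (highest prevalence).  `res.assignment`, `res.selection`
and `res.contingency` hold the labels, the k-scan trace and the 2×k
outcome table; `rc.train_cluster_classifier` / `rc.assign_clusters`
transfer the labels to new cohorts.

The same workflow is scriptable from a shell:

```bash
rfclust simulate --seed 1 --out cohort.csv
rfclust discover cohort.csv --outdir run/ --subsample 3000
rfclust train --rundir run/ --model-out model.joblib
rfclust assign validation.csv --model model.joblib --outdir val/
```

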