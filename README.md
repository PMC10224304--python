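# raasid

Identify antihypertensive drug (AHD) treatment from serum biomarkers of the
renin–angiotensin–aldosterone system (RAAS).

Population studies often lack reliable treatment documentation. When
angiotensin I, angiotensin II and aldosterone are measured in biobanked
serum, the characteristic shifts these drugs induce — ACE inhibitors (ACEi)
raise angiotensin I while depleting angiotensin II and aldosterone;
angiotensin-receptor blockers (ARB) raise both angiotensins while depleting
aldosterone — let unsupervised clustering reconstruct the most likely RAAS
treatment *a posteriori*. `raasid` packages this analysis for
epidemiologists and biostatisticians:

- **Synthetic cohort generator** — 8 age/sex-matched treatment groups
  (normotensive, untreated hypertensive, non-AHD, beta blockers, ACEi,
  ACEi+diuretics, ARB, ARB+diuretics; ~100 each, n = 800), log-normal
  biomarkers with drug-class profile shifts and known covariate effects.
- **Biomarker preparation** — natural-log transform, per-column z-scoring,
  pg/ml → pmol/L conversion, lower-limit-of-quantification (LLOQ) flagging
  with LLOQ/√2 substitution.
- **Cluster engine** — k-means, Ward hierarchical and fuzzy c-means over
  k = 2…6 (sensitivity extension to 8), scored by mean silhouette width
  s(i) = (b(i) − a(i)) / max(a(i), b(i)); PCA inspection; canonical
  relabeling by ascending mean log angiotensin I.
- **Agreement evaluation** — cluster × treatment cross-tabulation with
  group merging, sensitivity P(cluster | group) and specificity
  P(no cluster | no group) with exact Clopper–Pearson 95% CIs, and Cohen /
  weighted kappa κ_w = 1 − Σ w_ij p_ij / Σ w_ij e_ij.
- **Cluster profiling** — one-way ANOVA and Pearson chi-square across
  clusters with Tukey HSD follow-up.
- **Penalized mixed model** — for each log biomarker, a lasso on 13
  clinical fixed effects with crossed random intercepts for cluster and
  treatment group, penalty λ tuned by stratified 8-fold cross-validated
  MSE, and post-selection Wald inference from an unpenalized GLS refit.

## Worked example

```python
import numpy as np
import raasid
from raasid import prep

cohort = raasid.generate_cohort(raasid.default_config(seed=1))   # n = 800
panel = prep.standardize(prep.log_transform(
    prep.BiomarkerMatrix(cohort[list(raasid.BIOMARKERS)].to_numpy())))

report = raasid.select_clustering(panel.values, seed=1)
print(report.best_method, report.best_k,
      round(report.best_solution.silhouette, 3))
# kmeans 3 0.334

logm = np.log(cohort[list(raasid.BIOMARKERS)].to_numpy())
solution = raasid.canonical_relabel(report.best_solution, logm)
roles = raasid.identify_drug_clusters(solution.labels, logm)
table = raasid.crosstab(solution.labels, cohort["group"].to_numpy())
ba = raasid.binary_agreement(table, [roles["acei"]],
                             ["ACEi", "ACEi+diuretics"])
print(f"ACEi-like cluster: sens {ba.sensitivity:.0%}, "
      f"spec {ba.specificity:.0%}")
# ACEi-like cluster: sens 93%, spec 98%
```

The silhouette grid selects k-means with three clusters: a no-RAAS-drug-like
cluster (n = 323 here), an ARB-like cluster (n = 279) and an ACEi-like
cluster (n = 198). The ACEi-like cluster identifies combined ACEi treatment
with 93% sensitivity and 98% specificity on this synthetic cohort — the
ACEi signature (high angiotensin I, depleted angiotensin II) is the most
separable of the three profiles.

The penalized mixed model then asks which clinical characteristics still
predict each biomarker *after* the cluster and treatment structure is
absorbed by random intercepts:

```python
res = raasid.lasso_analysis(cohort, solution.labels, "ang1", seed=1)
print(round(res["cv"].lambda_min, 4))               # 0.0051
print(res["inference"].set_index("predictor").loc["age", "estimate"])
# -0.0208   (generating coefficient: -0.025 per year)
```

A command-line interface mirrors these stages:

```bash
raasid simulate --seed 1 --out cohort.csv
raasid all --input cohort.csv --seed 1 --out-dir results/
```

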