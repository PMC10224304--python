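# Methods

## The analysis problem

Eight treatment groups of roughly 100 adults each — normotensive, untreated
hypertensive, users of non-antihypertensive drugs, beta-blocker users, and
users of ACE inhibitors (ACEi) or angiotensin-receptor blockers (ARB) with
or without a thiazide diuretic — have serum angiotensin I, angiotensin II
and aldosterone measured in pmol/L. The question is operational: can an
unsupervised partition of the three biomarkers recover who is on a
RAAS-targeting drug, with the barcode-verified treatment classification as
gold standard, and which clinical characteristics still predict the
biomarkers once the cluster and treatment structure is removed?

## Synthetic cohort model

Real subject-level data of this kind are not redistributable, so the
package ships a generator whose draws have the statistical structure the
analysis assumes. Per group g and subject i:

- covariates: age, SBP, DBP, BMI ~ Normal with group-specific moments
  (the 800-subject design's printed means/SDs); HbA1c, glucose, total
  cholesterol, eGFR, sodium, potassium, cortisol ~ population-level
  Normals; sex ~ Bernoulli(group male fraction); diabetes ~
  Bernoulli(expit(logit(p_g) + 0.15·(BMI − 28))), coupling diabetes to BMI
  so the drug-treated clusters show the expected cardiometabolic gradient.
- log biomarkers: y_i = μ_g + B·(x_i − x_ref) + ε_i, ε_i ~ N(0, Σ),
  exponentiated to pmol/L.

Log-scale geometry (log-pmol/L): non-RAAS baseline μ = (4.3, 4.0, 4.9);
ACEi shift Δ = (+1.2, −1.5, −0.5); ARB shift Δ = (+1.0, +1.3, −0.5);
diuretic combinations multiply the shift by 1.25 (add-on therapy implies
stronger RAAS activation); residual SD 0.6 per log biomarker with
correlation 0.4 between the angiotensins and 0.15 with aldosterone. These
magnitudes are calibration choices — the source tables report only the
qualitative directions — picked so that three silhouette-optimal clusters
with realistic overlap emerge. The covariate coefficient matrix B defaults
to the reported observational associations (e.g. age −0.025/yr and male sex
+0.416 on log angiotensin I); `true_effect_table()` exposes it as ground
truth for recovery tests. Covariates are centered at reference values
(age 67, BMI 28, eGFR 77, SBP 136, DBP 85, others at their population
means) so μ_g is the expected profile of a reference subject.

One integer seed drives a single `numpy` generator for every draw; the
multivariate noise uses an exact PSD square root of Σ, so a zero covariance
yields exactly deterministic biomarkers (useful in tests).

What the generator does *not* emulate: treatment non-adherence, dosing and
titration, longitudinal blood-pressure dynamics, between-covariate
correlation beyond the BMI–diabetes link, and assay measurement error
beyond the log-normal residual. Passing tests therefore demonstrate that
the pipeline's machinery behaves correctly under the assumed structure, not
that real cohorts will show the same agreement levels.

## Preparation

Biomarkers are natural-log transformed (they are strongly right-skewed in
concentration units) and z-scored per column with population (denominator
n) SDs before clustering and PCA, the common convention when the scores
feed a Euclidean method. Unit conversion is value·1000/molar-mass
(pg/ml → pmol/L; masses 1296.5, 1046.2, 360.45 g/mol); the assay floor of
5 pg/ml maps to LLOQ = 3.9/4.8/13.9 pmol/L, and below-floor entries are
flagged and substituted by LLOQ/√2, the standard left-censoring convention
in analytical chemistry.

## Clustering and model selection

Three algorithms run over k = 2…6 (extension to 8 as sensitivity check):
k-means (k-means++ starts, 25 restarts, Lloyd iterations; scikit-learn),
agglomerative clustering with Ward linkage, and fuzzy c-means (authored
here: fuzzifier m = 2, tolerance 1e-6 on the membership change, 300
iterations max; non-convergence flags the result instead of raising). Every
(method, k) cell is scored by the mean silhouette width; the maximum wins,
with ties broken toward smaller k and then by method order k-means >
hierarchical > fuzzy. Larger silhouette is treated as better — the standard
definition. PCA of the standardized panel (correlation-matrix PCA) provides
the variance fractions and loadings used for inspection.

Canonical relabeling orders clusters by ascending mean log angiotensin I,
so cluster 1 is the no-RAAS-drug-like cluster. Because *both* drug classes
elevate angiotensin I, the ACEi-like and ARB-like clusters can have nearly
equal angiotensin I means under the default geometry; the two classes are
instead separated robustly by angiotensin II, which they shift in opposite
directions. `identify_drug_clusters()` therefore maps a 3-cluster solution
to pharmacological roles as: non-RAAS = lowest mean log ang I, ACEi-like =
lowest mean log ang II, ARB-like = highest mean log ang II. Reports that
speak of "the ACEi-like cluster" use this mapping.

## Agreement statistics

For a cluster set C and gold-standard group set G the 2×2 collapse gives
sensitivity tp/(tp+fn) and specificity tn/(tn+fp) with exact
Clopper–Pearson 95% intervals from beta quantiles (lower 0 at x = 0, upper
1 at x = n). Clopper–Pearson was chosen because it uniquely reproduces the
printed interval arithmetic of the reference worked examples (e.g. 54/99
gives (44, 65) after rounding, where a Wald interval gives (45, 64)).
Kappa on the 2×2 collapse is Cohen's kappa; for square multi-class tables a
weighted kappa with linear (|i−j|/(c−1)) or quadratic weights is provided,
with the Fleiss–Cohen–Everitt large-sample SE and a Wald CI. In the binary
collapse all weightings coincide, so the choice of weights is moot for the
per-(cluster, group) report. Report percentages are rounded half-up to
integers; raw proportions are retained alongside.

## Cluster profiling

Continuous characteristics: classic equal-variance one-way ANOVA across
clusters, reported as mean(SD) per cluster. Categorical: Pearson chi-square
without continuity correction. Variables with omnibus p < 0.05 (the global
significance level) get all-pairs Tukey HSD follow-up from the studentized
range distribution with pooled within-cluster variance. Constant variables
are reported as NA with a reason instead of a degenerate F test.

## Penalized linear mixed model

For each log biomarker y: 13 clinical fixed effects (age, sex as a male
indicator, BMI, HbA1c, glucose, cholesterol, eGFR, sodium, potassium,
cortisol, SBP, DBP, diabetes as 0/1), plus crossed random intercepts for
the 3-level cluster assignment and the 8-level treatment group. The random
terms absorb systematic between-cluster/between-treatment differences, so
the penalized fixed effects measure residual association.

Fitting alternates two exact blocks until the largest coefficient change is
below 1e-6 (500 outer iterations max):

1. given current BLUPs u, cyclic coordinate descent on the partial
   residual minimizes (1/2n)‖y − Zu − b₀ − Xβ‖² + λ‖β‖₁ over internally
   standardized predictors (mean 0, population SD 1), intercept
   unpenalized; the coordinate update is the soft-threshold operator
   S(z, λ) = sign(z)·max(|z| − λ, 0);
2. given β, the three variance components (σ²_cluster, σ²_treatment,
   σ²_residual) maximize the marginal likelihood of the fixed-effect
   residual, computed through Woodbury identities on the 11×11 core
   (O(q³) per evaluation regardless of n), with L-BFGS-B on log-variances;
   BLUPs are the ridge solution u = (Z'Z + σ²_e G⁻¹)⁻¹ Z'r. Variances at
   the optimizer's lower bound are reported as 0 and flagged as boundary
   estimates — with 3 and 8 levels they are weakly identified by design.

With the variance components held fixed the alternation is block
coordinate descent on one objective, and the recorded objective trace is
non-increasing (asserted in tests); with estimated components the trace is
reported but the objective itself changes between iterations.

λ is tuned on a descending grid of 50 log-spaced points spanning
[λ_max·10⁻³, λ_max] (λ_max zeroes every standardized coefficient), with
warm starts along the path. Cross-validation uses 8 folds stratified by
treatment group so every random-factor level appears in every training set
(a violating fold raises); held-out predictions include the training
BLUPs; λ_min is the grid argmin of mean validation MSE. A known property
of this rule, visible in the recovery simulations: the MSE curve's minimum
sits at small λ, so the selected model is prediction-optimal but retains a
fraction of null predictors — CV-min lasso is not selection-consistent.

Inference for the retained set is an unpenalized GLS refit of the mixed
model (iterating GLS and variance components to convergence), with Wald
SEs from (X'V⁻¹X)⁻¹. Predictors shrunk to zero are reported as "removed"
with no SE/p. This is naive post-selection inference, mirrored on the
reporting style of the reference analysis, and should be read as
approximate — no selective-inference correction is applied.

## Numerical and design choices

- Natural log throughout (the source states only "log-transformed").
- Standardization before k-means as well as PCA; a raw-log route is
  available by skipping `standardize`.
- Fuzzy memberships: coincident point/centroid pairs get full membership
  at that centroid; empty hard clusters after defuzzification are repaired
  by assigning the highest-membership point.
- Silhouette of singleton clusters is 0 by convention.
- Selection grid cells whose fit fails record the error and are excluded
  from the argmax rather than aborting the grid.
- All report percentages rounded half-up; significance level 0.05.

## Problem sizes used in the automated checks

Simulation-backed tests use the default n = 800 cohort: 20 seeds for the
selection-stability, agreement-pattern and parameter-recovery suites (the
recovery suite uses a 20-point λ grid), 2000 replicates for
Clopper–Pearson coverage at n = 50, and 5000 replicates for the ANOVA and
chi-square type-I error checks at 30 subjects per cluster. These sizes
keep each suite to a few minutes while leaving Monte-Carlo error well
below the margins being asserted.

## Known limitations

- The generator's profile magnitudes are calibration choices; absolute
  agreement statistics on synthetic cohorts are not estimates of any real
  cohort's values.
- Variance components over 3 and 8 levels are weakly identified; treat
  σ²_cluster and σ²_treatment as nuisance absorbers, not as estimands.
- Post-selection p-values are naive; no selective inference.
- CV-min λ overselects: expect some null predictors in the retained set.
- No GMM/density clustering, no bootstrap cluster stability, no
  non-Gaussian responses, no elastic net.
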