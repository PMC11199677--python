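# Methods

## Problem and scope

`methorigin` implements a tissue-of-origin prediction pipeline for
multi-class tumor cohorts profiled by DNA methylation (Infinium-450K-style
beta values in [0, 1]) or expression (FPKM-like nonnegative values). The
pipeline has five stages: data quality control, two-stage tissue-specific
feature selection, optional PCA, classification with eight standard model
configurations, and cross-validated evaluation. Because the original
pan-cancer cohort is external and not redistributable, the package ships a
synthetic-cohort generator with planted class-specific markers; all tests
and the acceptance script run against planted ground truth, so they verify
the *pipeline's* behaviour (recovery, calibration, leakage safety), not
performance on real tumors.

## Synthetic cohorts

Methylation beta values are logit-normal: each feature has a background
mean drawn from a 50/50 bimodal mixture with modes near 0.2 and 0.8
(jittered on the logit scale, SD 0.3), mimicking the canonical genome-wide
450K beta distribution. Sample noise is Gaussian on the logit scale
(default SD 0.5, roughly 0.08–0.12 SD on the beta scale depending on the
mean) and values are clipped to [1e-6, 1 − 1e-6]. Each class receives a
disjoint set of markers whose class-conditional mean is shifted by ±delta
*on the beta scale* before noise; direction is a fair coin, falling back
to the feasible direction when the coin would leave (0, 1) — so hypo-mode
markers at large delta are predominantly hypermethylated in their class.
Missing values are masked uniformly at random. Expression cohorts are
log-normal (log2 baseline N(3, 2), inter-sample SD `dispersion`, default
1.0) with ±`log2fc` marker shifts and no missing values, since expression
matrices are typically complete.

Defaults are the desk-scale study conditions used throughout the tests:
6 classes × 100 samples, 5,000 features, 50 markers per class,
delta = 0.3, sd_logit = 0.5, no missing values unless a test injects
them. A 20-class × 337-sample shape mirroring a real pan-cancer cohort is
available (`FULL_COHORT`, `--full-cohort`). Delta = 0.3 beta units is a
typical magnitude for strong tissue-specific differential methylation;
with the default noise the realized class-mean gap shrinks to ≈ 0.29
(logit-normal means are pulled toward 0.5), which the generator tests
account for. What the generator does **not** emulate: spatial correlation
among neighbouring CpGs, batch/plate effects, class-specific missingness,
type-I/type-II probe chemistry differences, and tumor purity variation.
Passing tests therefore demonstrate correct mechanics and sensible
statistical behaviour under idealized noise, not clinical accuracy.

## Preprocessing

* **Class-size QC** — classes need *more than* `min_class_size` samples
  (default 100); the rule is strict at the boundary.
* **Missingness filter** — features with a missing fraction *strictly
  greater* than 30% are removed (exactly 30/100 survives).
* **KNN imputation** — feature-wise, the convention of the canonical 450K
  KNN impute: donors for a missing cell are the K features nearest in
  plain Euclidean distance over mutually observed samples, and the
  imputed value is the mean of the donors' values at that sample, hence
  always inside the donors' range (and [0, 1] for beta data). K defaults
  to 5. Distance ties break by feature-ID lexicographic order so results
  are deterministic; if fewer than K donors observe the needed sample all
  available donors are used, and with none the feature's own observed
  mean stands in. The imputer is hand-written because the scikit-learn
  imputer rescales its NaN-aware distances by the co-observation count
  and has no deterministic tie-break, which breaks both the contract
  above and exact reproducibility; everything else in the package
  delegates to scikit-learn/SciPy/statsmodels.

The full pass (QC → filter → impute) is idempotent and never rewrites an
observed cell.

## Feature selection

Stage 1 screens each (feature, class) pair with a two-sided **Welch**
t-test of the class against all other classes pooled — Welch rather than
pooled-variance Student, because one-vs-rest groups are strongly
heteroskedastic — with Benjamini–Hochberg adjustment applied per class
across features and a q < 0.01 cut. A feature survives if significant for
any class. Constant features get p = 1. The per-class (rather than
pooled) adjustment treats each tissue's marker discovery as its own
family, matching the one-vs-rest framing.

Stage 2 ranks the survivors by the MFMD criterion
(Maximum-F-statistic-Maximum-Distance):

    mfmd(f) = w_s · F_norm(f) + w_d · ED_norm(f),  0 < w_s, w_d ≤ 1

where F is the one-way ANOVA F-statistic of feature f across classes
(relevance) and ED is f's mean Euclidean distance to every other
candidate's sample-vector (redundancy: larger distance = less redundant).
F and ED live on incomparable scales — F is unitless and unbounded, ED is
in matrix units — so both are min-max normalized to [0, 1] across the
candidates before weighting; a degenerate spread (all values equal)
defines the normalized score as 0 for every candidate. Default weights
are w_s = w_d = 1. Ranking is by descending combined score with ties
broken by higher F_norm, then feature ID. ED is scored one-shot against
all candidates rather than greedily against already-selected features:
the one-shot form is deterministic, order-free, and consistent with
rank-then-cut selection. A `redundancy_sign=-1` switch flips the
distance term for the minimum-distance reading of the criterion, since
"maximize distance" and "prefer low redundancy scores" are both
defensible conventions; the default maximizes distance.

Numerical choices: F is computed from between/within sums of squares
with reductions along each feature's contiguous axis, so a matrix column
yields exactly the same float as the same data as a 1-D vector; zero
within-group variance yields F = 0 when group means agree and a finite
cap of 1e12 otherwise (keeping the normalization finite); mean distances
use the direct sum-of-squared-differences algorithm up to 512 candidates
and the BLAS Gram identity above that (the two agree to relative 1e-9;
the direct path is additionally exact against a loop oracle).

## Dimensionality reduction

Centered PCA (no unit-variance scaling — beta values already share one
scale) with samples as observations. The kept component count is the
smallest m whose cumulative explained variance ratio strictly exceeds
the target (default 0.95), so removing the last kept component drops
below target. Loading signs are normalized (largest-magnitude entry
positive) for reproducibility. PCA is fitted on training samples only
wherever the pipeline uses it; the profile-level switch applies it to
methylation data, while expression profiles are fed raw.

## Classifiers

Eight configurations behind one contract (fit on samples × features,
predict labels and per-class probabilities summing to 1):

| name | configuration |
|------|---------------|
| RF | random forest, 200 trees, soft voting (per-tree probability average) |
| SVM | linear kernel, one-vs-rest; softmax over decision values as pseudo-probability |
| KNN | K = 5, Euclidean |
| DT | CART, Gini impurity, unpruned |
| LDA | linear discriminant analysis, one-vs-rest |
| LASSO | L1-regularized logistic regression, one-vs-rest, C = 1.0 |
| NN | feed-forward, one hidden layer of 128 ReLU units, backpropagation, ≤ 500 epochs |
| NBC | Gaussian naive Bayes |

Model fitting delegates to scikit-learn; the package's contribution is
the faithful configuration, the uniform probability contract, and the
feature-signature guard (predict rejects inputs whose columns differ
from training). Open parameters with no published value — LASSO strength,
NN topology and epoch budget, the NBC likelihood — use the defaults above
and are exposed in `RunConfig.classifier_params`. The SVM softmax is a
normalization convention, not a calibration; the LASSO's one-vs-rest
probabilities are renormalized across classes.

## Evaluation

Overall accuracy is correct/total. Per class i, precision is correct
class-i calls over all class-i calls and recall is correct class-i calls
over true class-i samples; a class never predicted gets precision 0 with
a flag, and predicted labels absent from the truth are excluded with a
warning. Cross-validation uses stratified folds (stratification keeps
per-class recall stable when many classes are present) with pooled
(micro) confusion accounting, so the support-weighted mean of per-class
recalls equals the overall accuracy exactly — an identity the tests
enforce on random vectors.

The default whole-pipeline protocol is a stratified 50/50 split with
feature ranking on the training half and stratified 5-fold CV on the
held-out half restricted to the chosen features. This honors the
published design (half split, then CV in the testing cohort) while
remaining leakage-safe; whether the original ranked features inside or
outside the CV is ambiguous, so a `whole_data_cv` switch provides the
alternative reading. Leakage safety is verified by a canary: an extra
feature encoding the true label on held-out samples only (noise on the
training half) is never selected and does not raise accuracy relative to
a pure-noise control feature.

The marker-curve driver evaluates CV accuracy at top-k prefixes of a
ranked list over the default grid {10, 50, 100, 250, 500, 1000, 2000};
on planted cohorts the curve rises sharply at small k and levels off,
and the acceptance suite asserts the increment ordering rather than any
absolute value.

## Problem sizes

Tests and the acceptance script run on the 6 × 100 default cohort
(5,000 features), with smaller cohorts for unit tests and 20 replicate
seeds for distributional checks; these sizes are the package's
desk-scale study conditions, chosen so the planted-signal properties
(recovery ≥ 80% in the top 300, LASSO ≥ 90% pooled CV accuracy on the
top 500) are comfortably identifiable under the default noise.

## Known limitations

* The synthetic generator's independence across features makes the
  redundancy term (ED) less decisive than on real, block-correlated
  methylation data; MFMD's behaviour under heavy inter-CpG correlation
  is exercised only via the duplicate/identical-feature degenerate tests.
* The screen's FDR control is verified marginally under a pure null;
  dependent features would require a dependence-robust adjustment.
* No probe-level normalization (BMIQ/quantile) or batch correction is
  implemented; inputs are assumed comparable across samples.
* Expression profiles are classified on raw values without scaling;
  scale-sensitive models (KNN, NN) will underperform there by design.
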