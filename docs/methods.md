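# Methods

`relifex` implements a data-driven workflow for characterizing
post-treatment tinnitus-related distress from baseline questionnaire
features: exploratory correlation analysis, cross-validated multi-classifier
training, an iterative model-reliance feature-elimination wrapper, and
post-hoc additive-attribution analytics. Because the clinical cohort the
workflow was designed around is not publicly deposited, the package ships a
seeded synthetic cohort generator that emulates that cohort's statistical
structure, so every stage is exercised end to end without any download.
This note documents the models, the defaults and why they were chosen, and
what the synthetic experiments do and do not demonstrate.

## Outcome and target definition

Tinnitus-related distress is a continuous questionnaire total score on
[0, 84], measured before (T0) and after (T1) treatment. The binary target
is the discretization of the **T1** score at cutoff 46: scores in [0, 46]
are *compensated*, scores in (46, 84] *decompensated*. Only baseline (T0)
features are ever passed to a classifier; the pipeline audits the predictor
set for outcome columns and refuses to run if any leaks in.

## Synthetic cohort generator

The generator emulates the empirical skeleton of a multi-questionnaire
cohort rather than any questionnaire's item content.

**Correlation structure.** Features are derived from unit-variance latent
Gaussians with a two-level factor structure: a cohort-wide factor `W` and
one factor per feature block. A feature in block *b* with polarity sign
`s_b` and within-block correlation `rho_b` is

    x = s_b sqrt(g) W + sqrt(rho_b - g) G_b + sqrt(1 - rho_b) e,

with `g` the magnitude of the between-block correlation. Within-block
correlation is exactly `rho_b`; features in blocks of opposite polarity
correlate at `-g`. The study-scale default (`study_like_spec`) uses a
114-feature negatively polarized block and a 47-feature positively
polarized block (`rho_b = 0.45`, between-block −0.3), mirroring the two
anti-correlated groups of negatively and positively polarized scales that
dominate real questionnaire batteries, plus 26 dichotomous
sociodemographic indicators, 10 per-questionnaire completion-time features
and 8 unstructured continuous features — 205 features for 1,416 patients.

**Scale mapping.** Likert items are equal-probability quantile bins of the
latent Gaussian (5 levels by default), which preserves rank correlation up
to discretization loss (a latent correlation of 0.5 maps to a Likert
Spearman correlation of roughly 0.45–0.48). Dichotomous features threshold
the latent at zero; completion times are log-normal (`exp(3 + 0.5 z)`
seconds, i.e. ~20 s median with realistic right skew).

**Planted effects.** The T1 score is built from a linear predictor
`sum_k c_k g(x_k)` over declared informative features, where `g` is the
identity for linear effects and, for "J-shaped" effects, a dip-then-rise
link with its minimum at 30% of the feature range:

    g(v) = (v - 0.3r)^2 / r^2 + 0.15 max(0, 0.3r - v) / r,   r = range.

On a 0–10 visual-analogue-type scale the dip sits near 3, matching the
curvilinear dependence profiles this kind of model tends to reveal for
impairment and loudness ratings. The standardized predictor plus Gaussian
noise (`noise_sd`, default 0.8 at study scale — signal-dominant but far
from deterministic) is mapped to [0, 84] by a monotone piecewise-linear
transform that sends the (1 − prevalence) sample quantile to the cutoff,
so the decompensated fraction matches the target prevalence (default 0.32)
up to sample granularity.

**T0 from T1.** `T0 = clip(T1 + |N(6, 4)|, 0, 84)`: treatment lowers
distress on average, producing net decompensated-to-compensated
transitions and a T1-on-T0 regression slope below 1 without modelling the
treatment itself.

**Seeding.** A single spec seed fans out to fixed documented offsets
(latent draw +11, outcome noise +23, T0 offset +37), so sub-streams are
independent and every table is bit-reproducible.

**What the generator does not emulate:** item-level psychometrics of the
actual questionnaires, missing data (the design is completers-only),
floor/ceiling effects beyond clipping, and any treatment-effect
heterogeneity. Passing the planted-recovery and null-calibration
experiments therefore shows the *procedure* behaves correctly under known
ground truth; it does not validate clinical conclusions on real patients.

## Preprocessing and baseline comparison

Ordinal Likert items are treated as continuous. Multi-level categoricals
expand to exhaustive dichotomous indicators (the indicators of one
categorical sum to 1 per row and the encoding map records the expansion).
Rows with missing values are rejected rather than imputed. The baseline
summary compares the two outcome groups feature by feature with a
caller-assigned test — Welch t-test, Mann–Whitney (normal approximation
with tie correction; exact enumeration for small tie-free samples), or
Pearson chi-squared (no continuity correction by default, flag available)
— under Bonferroni correction, `p_crit = alpha / m` over the `m`
comparisons actually made. The test assignment is caller-supplied because
no rule cleanly derives it from scale type alone; the pipeline default
uses chi-squared for dichotomous features and Mann–Whitney otherwise.

## Correlation analytics

All correlations are Spearman with average ranks for ties. Constant
columns yield an explicitly undefined (NaN) correlation — never a silent
zero — and are excluded from questionnaire medians. Heatmap ordering comes
from agglomerative hierarchical clustering with complete linkage on the
*signed* distance `1 − rho`: sign sensitivity is what separates positively
from negatively polarized feature groups into distinct branches
(`1 − |rho|` would merge them). SciPy's condensed-matrix linkage resolves
equal-distance merges deterministically by pair index, so the leaf order
is stable across calls. Feature–distress analytics report per-feature
correlation at T0 and T1, top-k magnitude lists per time point, top-k by
magnitude shrinkage `|rho_T0| − |rho_T1|`, and per-questionnaire medians
over an explicit membership map.

## Classifier training

The roster covers the usual algorithm families for tabular questionnaire
data — gradient boosted trees (xgboost), random forest, L1- and
L2-penalized logistic regression, distance-weighted k-NN, Gaussian naive
Bayes, CART, SVM, and a single-hidden-layer neural net — each exposing
predicted probabilities so that reliance scores and threshold metrics
share one score contract. Scale-sensitive learners are wrapped in a
standardization pipeline.

Hyperparameters are selected by grid search scored with mean out-of-fold
AUC over stratified k-fold cross-validation (k = 10 by default; the same
fold assignment is reused for every grid point). AUC is the tie-corrected
probability that a random positive outranks a random negative
(Mann–Whitney U / (n+ · n−)). The winning configuration reports per-fold
AUCs, their mean, SD (ddof = 1) and a normal-approximation 95% CI
(mean ± 1.96 SD/√k — the SD is across folds), and is refit on all rows.

Cross-validation is deliberately *flat* (not nested): the reported AUC of
a tuned configuration is the same quantity used to select it, so it is
optimistically biased. This mirrors the single-number protocol the
workflow is designed to reproduce; an honest outer estimate would require
nested CV, which the API leaves to the caller by re-running
`tune_and_evaluate` on held-out data.

## Model reliance and incremental feature elimination

Model reliance (MR) scores a fitted model's dependence on feature *f* as
the ratio of the classification error after randomly permuting *f*'s
column to the error on unpermuted data, averaged over `n_perm = 10`
independent seeded permutations:

    MR(f) = e_perm / e_orig,   e = CE(y, model(X)).

Numerical choices:

* **CE** is 0/1 misclassification at probability 0.5; an unqualified
  "classification error" is conventionally 0/1 loss. AUC-based reliance
  (`loss="auc"`) is available behind a flag.
* **Smoothing**: `MR = (e_perm + eps) / (e_orig + eps)` with
  `eps = 0.5/n`, keeping the ratio finite on perfect training fits while
  leaving it exactly 1 whenever the two errors are equal — in particular,
  MR is exactly 1 for a feature the model provably ignores.
* MR is computed on the full training set with the refit model. This is
  the cheap, slightly leaky convention the wrapper is built around; an
  out-of-fold variant would cost one model per fold per iteration.

The incremental feature-elimination (IFE) wrapper starts from the full
feature set, and in each iteration tunes the classifier on the current set
(hyperparameters are re-tuned every iteration), refits on all rows,
computes MR for every current feature, and retains exactly the features
with MR > 1 (strict inequality; MR ≤ 1 means permutation did not hurt).
It stops when no MR exceeds 1, when the retained set equals the current
set, or at `max_iter` (default 25 — a cheap safeguard; strict shrinkage
already bounds the trace by p). When the retained set equals the current
set, the wrapper stops *without* re-recording a duplicate iteration: the
next iteration would train the identical model, so the trace ends at the
last informative record with reason `feature_set_unchanged`.

The best overall model is the (classifier, iteration) pair with maximal
mean CV AUC across all traces; ties break toward fewer features, then by
roster order.

On training data an overfit learner can show MR > 1 even for noise
features (permuting anything it memorized hurts), so early iterations
shrink the set mostly by dropping features whose permutation is neutral;
the planted-recovery experiment checks that genuinely informative features
survive to the final set while performance stays within 0.02 AUC of the
full-feature model, and the null experiment checks that on pure noise the
final cross-validated AUC stays compatible with chance.

## Additive attributions

All attribution backends return per-instance additive attributions on the
log-odds scale with local accuracy: prediction = phi0 + sum_j phi_j, phi0
the expected margin over the background.

* **Tree backend** (gradient boosted trees): exact Shapley values of the
  tree-path value function, in which the expectation of a coalition S
  descends each tree following the instance at splits on features in S
  and averaging both children by their training cover otherwise (the
  training data enters as background through the node covers, so no
  explicit background sample is needed). Because each leaf's value
  function involves only the features on its root-to-leaf path, the
  Shapley sum reduces to a per-leaf enumeration of path-feature subsets —
  exact, float64, and O(leaves · 2^depth) per tree, cheap for the shallow
  trees the grids use (depth ≤ 4). The booster's own float32 contribution
  predictor implements the same quantity and serves as an independent
  cross-check in the tests.
* **Linear backend** (logistic regression, possibly behind a scaler):
  closed-form interventional Shapley `phi_j = w_j (x_j − E_bg[x_j])` on
  the model's internal feature scale; exact.
* **Sampling backend** (anything else): permutation-sampling interventional
  estimator over an explicit background (seeded subsample of 100 rows by
  default, 32 feature orderings; exhaustive — hence exact — for ≤ 5
  features). Telescoping marginal contributions make local accuracy hold
  exactly even for sampled estimates; the per-value Monte-Carlo standard
  error is recorded as the result's tolerance.

Global importance is `A(j) = mean_i |phi_ij|` (the mean, which induces the
same ranking as the sum over a fixed instance set), sorted descending with
index tie-break. Explanation clustering applies complete-linkage
agglomerative clustering to the attribution rows under Euclidean distance
(the metric is a convention choice) cut at k = 5 by default, reporting
each cluster's mean attribution row-sum. Dependence profiles pair feature
values with attributions and overlay a LOWESS trend (span 2/3, tricube
weights, 3 robustness iterations — classic defaults). The marginal
importance curve re-tunes the classifier on importance-ranked feature
prefixes of size 1..m. The correlation network connects selected features
with |rho| ≥ 0.5 (boundary inclusive) and drops isolated nodes.

## Pipeline and reproducibility

A single YAML configuration drives all stages; unknown keys are errors,
because a silently ignored grid entry is the likeliest user mistake. One
master seed fans out to stage seeds via fixed offsets; two runs with the
same configuration produce byte-identical numeric artifacts. The manifest
records the configuration hash, seed, package version and every written
file; a stage failure persists a partial manifest naming the failed stage.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run entirely on generated data
at sizes chosen to exercise every code path at desk scale: the
study-scale run uses 1,416 patients × 205 features with gradient boosted
trees and ridge logistic regression under reduced grids; the
planted-recovery experiment uses 1,000 patients with 5 informative + 50
noise features over repeated seeds; the null calibration uses 500
patients × 30 noise features. Exhaustive oracles (permutation
enumeration, coalition enumeration) run at 5 rows and ≤ 4 features where
enumeration is exact.

## Known limitations

* Flat CV makes every reported AUC an optimistic estimate of
  generalization; the elimination wrapper additionally selects features on
  training-set reliance, a second source of optimism that the null
  experiment bounds empirically at the shipped problem sizes.
* MR on training data conflates memorization with signal for flexible
  learners; the wrapper relies on the retention rule, not the MR
  magnitude, being meaningful.
* Tree attributions use the cover-based (path-dependent) value function,
  not an explicit interventional background; for strongly correlated
  features the two conventions can differ.
* The sampling attribution backend scales as
  O(instances · orderings · features · background) model calls and is
  intended for the smaller models in the roster, not for wide feature
  sets.
* The synthetic generator's Gaussian copula cannot produce the skewed,
  zero-inflated item distributions of real questionnaire data; effect
  sizes recovered on synthetic cohorts do not transfer to clinical ones.
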