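# Methods

This note documents the models and procedures implemented in `srpnet`,
the defaults they use, and the choices made where the design was
genuinely open.

## Preprocessing

Raw cohort files are CSV/TSV with a header row; a YAML schema declares
each column's kind (binary / ordinal / continuous) and, for textual
columns, a text→integer encoding that must map onto consecutive codes
starting at 0 (e.g. education illiterate=0 … postgraduate=4; marriages
single=0, once=1, remarried=2).  Unknown category strings are hard
errors naming the column and value.  Missing values are a hard error by
default with an opt-in row-drop flag: the pipeline assumes complete-case
screening data, and silent imputation would change the downstream
statistics.

Every column is min-max normalized to [0, 1], x′ = (x − min)/(max − min),
independently per column.  A constant column has zero range; it is set
to all zeros with a warning rather than dropped, so column indices stay
stable and the level-1 filters discard it.  The per-column (min, max)
pairs are persisted as JSON and reused to transform held-out rows
(clipped to [0, 1]), so test data never leaks into the training
statistics.

## Level-1 screening

Four scores per feature, each with its own kept rule:

- **Chi-square** (discrete features only): χ² = Σ (A − E)²/E over the
  feature-by-label contingency table, df = (r−1)(c−1), no continuity
  correction; kept when p ≤ α (default 0.05).  Empty contingency rows
  and columns are dropped before expectations are formed.  The
  uncorrected statistic keeps the type-I rate of the p ≤ 0.05 rule at
  its nominal 5% on null features, which the test suite checks by
  simulation.  Continuous columns are skipped with a warning.
- **Pearson correlation** against the ordinal label codes; kept when
  |ρ| ≥ τ (default 0.1).  Constant columns score 0 with a warning.
- **Lasso** and **elastic net** on the squared-error objective
  (1/2n)Σ(yᵢ − θ₀ − Σxᵢⱼθⱼ)² + λ[α·Σ|θⱼ| + (1−α)·Σθⱼ²], fit with
  scikit-learn coordinate descent on labels coded 0..K−1 and rescaled to
  [0, 1]; kept when θⱼ ≠ 0.  The penalty strength λ defaults to 5-fold
  cross-validated choice; the L1 proportion α defaults to 0.5 (α = 1
  recovers the Lasso exactly, which the suite asserts to 1e−8).  At
  α = 0 (ridge) exact zeros are non-generic, so the kept rule uses a
  1e−8 magnitude tolerance instead.

The multi-category label is treated as a single ordinal variable
(low < medium < high < TIA < stroke) for the correlation and regression
scores.  This is the one place the category ordering matters; the
chi-square score and everything downstream are ordering-free.

The candidate set is the union of the four kept sets in original column
order; an empty union is an error advising threshold relaxation.

## Level-2 subset search

All 2ⁿ − 1 non-empty candidate subsets are enumerated in (size,
lexicographic) order, guarded at n ≤ 20 by default.  Each subset is
scored by seven classifiers — SVC, k-nearest neighbours, decision tree,
gradient-boosted trees, random forest, AdaBoost, Gaussian naive Bayes —
using stratified k-fold cross-validated micro precision (default k = 5)
with a pinned seed, and subsets are ranked by the unweighted mean over
the seven.  Ties break toward smaller subsets, then lexicographic
order, so adding an uninformative column never wins a tie.  Scoring is
deterministic for a fixed seed and independent of the joblib worker
count, because each subset's CV seed is fixed before dispatch.

Two frozen hyperparameter profiles exist for the classifier bank:
`default` (scikit-learn defaults) and `fast` (decision trees capped at
depth 6; GBDT 10 estimators of depth 2; random forest and AdaBoost 10
estimators).  The `fast` profile exists because an exhaustive sweep
costs (2ⁿ − 1) × 7 × k model fits — at n = 8 and k = 2 about 3,600 fits
per run — and the recovery properties it is used to demonstrate
(informative subsets beating noise, redundant copies losing to their
parents) are not sensitive to ensemble size.  Cohorts larger than a cap
(default 20,000 rows) are stratified-subsampled before the sweep.

For candidate sets beyond the enumeration guard, a greedy forward
search (O(n²) subset evaluations) is provided as an explicit fallback;
its result object is marked non-exhaustive.

## The fused predictor

Input is the normalized feature vector x ∈ [0,1]^d of one subject.

- **Self-attention branch.**  Each feature j becomes a token
  tⱼ = xⱼ·eⱼ + uⱼ with learned per-feature embedding vectors eⱼ, uⱼ of
  width c (default 32).  Single-head scaled dot-product attention,
  softmax(QKᵀ/√d_k)V with Q = TW_Q, K = TW_K, V = TW_V (c×q, q default
  32), mixes the d tokens; the outputs are mean-pooled and linearly
  projected to the shared embedding H_t (width 32).  Tokenizing
  *features of one subject* — rather than subjects of one batch — keeps
  inference batch-independent: a subject's prediction cannot depend on
  who else is in the batch.
- **Fully connected branch.**  H_c = W₂·ReLU(W₁x + b₁) + b₂ with one
  hidden layer (default width 64), projected to the same shared width.
- **Attention gate.**  s_t = w_a·tanh(W_g H_t + b_g) and likewise s_c;
  (a_t, a_c) = softmax(s_t, s_c) per subject, so a_t + a_c = 1 always.
  The gate is per-subject because its inputs vary per subject; a global
  gate would throw away exactly the adaptivity it exists to provide.
  The fused embedding L(a_t·H_t + a_c·H_c) feeds a linear K-way head.
- **Training.**  Cross-entropy on softmax logits (optional
  inverse-frequency class weights, off by default), Adam with fixed
  learning rate 0.001, batch size 256, stratified 80/20 train/test
  split, up to 100 epochs.  All forward/backward passes are hand-written
  numpy; a finite-difference gradient check in the test suite covers
  every parameter tensor in all three gate modes.  Because 100 is a
  *maximum* epoch count, the reported model is the checkpoint with the
  best held-out micro precision seen during training (ties resolve to
  the earlier epoch); selecting on the same held-out split that is later
  reported is mildly optimistic, which is acceptable for the comparative
  uses the package puts it to (branch ablations, feature ablations) and
  is stated here so nobody mistakes it for an unbiased generalization
  estimate.
- **Ablations.**  `gate_mode="fcn_only"` forces a_t ≡ 0 (pure FCN) and
  `"attention_only"` forces a_c ≡ 0 (pure attention branch); both are
  first-class training modes used by the ablation checks.

Depth and head count are deliberately minimal (one encoder block, one
head): the feature counts involved (≤ ~16 tokens) give deeper stacks
nothing to attend over, and a small model keeps desk-scale training in
seconds.

## Metrics

All scalar metrics derive from the K×K confusion matrix (rows true,
columns predicted): micro precision = ΣTP/(ΣTP + ΣFP) (equal to
accuracy, and identically equal to micro F1, in single-label K-way
prediction — the suite asserts the identity); macro precision is the
unweighted mean of per-category precision with never-predicted
categories contributing 0 under a warning; Cohen's kappa uses
p_e = Σᵢ rowᵢ·colᵢ/n².  ROC is one-vs-rest per category plus a
micro-average curve over the flattened one-hot/probability pairs, with
trapezoidal AUC.  The leave-one-feature-out probe retrains the fused
model once per removed feature and ranks features by micro-F1 drop
against the all-features baseline.

## Synthetic cohorts

The generator emulates the *structure* of a large stroke-screening
registry, not its joint distribution: 26 features named and typed after
the registry's columns (binary risk factors at the registry prevalences,
ordinal education/marriage counts, continuous age and regional-climate
variables), and five categories at the registry's proportions
(≈ 0.711 / 0.144 / 0.099 / 0.027 / 0.020).  Six binary risk factors
(hypertension, stroke history, atrial fibrillation, LDL-C, diabetes,
smoking) are planted informative with unit weight on the latent risk
score s = Σ wⱼzⱼ (standardized features); four features are planted
redundant — continuous noisy copies of informative parents at target
correlation 0.9 — and sixteen are pure noise.  Labels are drawn from a
multinomial logit with category slopes 0, 0.5, 1, 1.5, 2 on s
(slope_scale 2.0, chosen so the planted signal is clearly detectable at
n = 5,000 without being trivially separable) and intercepts tuned by a
coordinate-wise log-adjustment search against a pilot sample (≤ 10⁵
rows) until the marginal proportions are within 0.005 of target;
unreachable targets raise with the achieved proportions.  With
`separable=True` labels are instead deterministic quantile bands of s,
which makes the categories linearly separable — the regime used to
verify that the network optimizer actually works.

What the generator does **not** emulate: geographic/climatic joint
structure between the province-level columns, survey-design effects,
measurement error, or real-world effect-size heterogeneity.  Passing
recovery tests on these cohorts therefore demonstrates that the
machinery finds planted structure under realistic imbalance and
redundancy, not that it would select the same features on real
registry data.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own desk-scale defaults: level-1 recovery runs
20 cohorts of n = 5,000 (full 26-feature spec); the level-2 redundancy
check runs 20 exhaustive 255-subset sweeps over 8 candidates (4 planted
parents + their 4 copies) at n = 400 with 2-fold CV and the `fast`
profile; the network checks use n = 2,000 separable cohorts with 5
seeds and all three gate modes.  The chi-square calibration simulates
500 null features at n = 2,000 (binomial standard error ≈ 1%, well
inside the ±2 percentage-point check).

## Known limitations

- Exhaustive search is exponential by design; beyond n = 20 candidates
  only the greedy fallback is practical, and it carries no optimality
  guarantee.
- The ordinal coding of the label for Pearson/Lasso/elastic-net scores
  assumes the risk categories are meaningfully ordered; if TIA/stroke
  are better treated as nominal, only the chi-square filter and
  everything from level-2 onward remain fully appropriate.
- The squared-error Lasso/elastic-net on an ordinal-coded label is a
  screening device, not a calibrated risk model; its kept sets feed the
  wrapper stage rather than being interpreted as effect estimates.
- Training the network on strongly imbalanced cohorts without class
  weights optimizes overall (micro) precision; rare-category recall can
  be poor.  Inverse-frequency weights are available but off by default.
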