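# srpnet

Two-level feature selection and an attention-fused dual-branch neural
network for multi-category clinical risk prediction on tabular cohorts.

## The problem

Population stroke screening assigns each subject one of several risk
categories (low / medium / high risk, transient ischemic attack, stroke)
from a few dozen mixed binary / ordinal / continuous features —
hypertension, stroke history, atrial fibrillation, lipid status,
lifestyle, regional climate, and so on.  Two things make this hard:
the screening features are partly redundant (e.g. a variable that is
little more than a noisy proxy of another risk factor), and the category
distribution is heavily imbalanced (roughly 71 / 14 / 10 / 3 / 2 percent).
`srpnet` packages a complete, reproducible pipeline for this setting:

1. **Level-1 screening** scores every feature four ways — chi-square
   test (kept when p ≤ 0.05), Pearson correlation with the ordinal risk
   code (kept when |ρ| ≥ τ), and Lasso / elastic-net coefficients on the
   squared-error objective

   min<sub>θ</sub> (1/2n) Σᵢ (yᵢ − θ₀ − Σⱼ xᵢⱼθⱼ)² + λ[α Σⱼ|θⱼ| + (1−α) Σⱼθⱼ²]

   (kept when θⱼ ≠ 0; α = 1 is the Lasso, α = 0.5 the default elastic
   net).  The union of the four kept sets is the *candidate set*.
2. **Level-2 wrapper search** enumerates all 2ⁿ − 1 non-empty candidate
   subsets and scores each with seven classical classifiers (SVM, KNN,
   decision tree, GBDT, random forest, AdaBoost, Gaussian naive Bayes)
   by stratified cross-validated micro precision; the subset with the
   best mean score wins, which strips redundant copies the level-1
   filters cannot see.
3. **The fused predictor** runs a per-feature-token self-attention
   branch, softmax(QKᵀ/√d_k)V, and a one-hidden-layer fully connected
   branch over the same normalized feature vector, then gates the two
   embeddings per subject with a learned attention pair
   (a_t, a_c) = softmax(w_a·tanh(W H + b)), a_t + a_c = 1, before a
   linear K-way softmax head.  Training is Adam (lr 0.001), cross-entropy,
   80/20 stratified split, up to 100 epochs, implemented in pure numpy
   with hand-derived gradients and bit-reproducible seeding.

Evaluation uses micro precision, micro F1 (identical to micro precision
for single-label prediction), macro precision, Cohen's kappa
κ = (p_o − p_e)/(1 − p_e), and one-vs-rest ROC/AUC.

A synthetic cohort generator produces screening-registry-like data (26
mixed-type features, five imbalanced categories, planted informative /
redundant / noise features) so every stage is testable with a known
ground truth and no external data.

## Worked example

```python
import numpy as np
from srpnet import (default_csdc_spec, generate_cohort, minmax_normalize,
                    select_level1, search_optimal, FusionClassifier, FusionConfig)

table, labels, truth = generate_cohort(default_csdc_spec(5000, seed=1))
table, _ = minmax_normalize(table)

report = select_level1(table, labels, seed=1)
print(len(report.candidate_set), "candidates:", report.candidate_set[:6], "...")

search = search_optimal(report.candidate_set[:8], table, labels,
                        seed=1, cv=2, profile="fast")
print("best subset:", search.overall_best.subset,
      "mean micro precision %.4f" % search.overall_best.mean_score)

res = FusionClassifier(table.select(search.overall_best.subset), labels,
                       FusionConfig(seed=1)).fit()
print(res.summary())
```

On this seed the run prints:

```
13 candidates: ['AG', 'Gender', 'Occupation', 'HS', 'HYP', 'AF'] ...
best subset: ('HS', 'HYP', 'AF', 'LDL-C', 'Smoking') mean micro precision 0.7358
Attention-fusion risk classifier
================================================
subjects (train/test)          4001/999
features                       5
categories                     5
gate mode                      learned
parameters                     9221
epochs                         100
learning rate (Adam)           0.001
selected epoch                 45
final training loss            0.7124
held-out micro precision       0.7528
================================================
```

All six planted informative risk factors land in the 13-feature
candidate set; the wrapper search keeps five planted risk factors and
drops the redundant copies that rode in on their correlation with the
parents; the fused network's held-out micro precision sits at the
ceiling the planted label noise allows (labels are drawn from a
multinomial logit, so even the true model cannot score 1.0 here).

A `srpnet` command-line tool exposes the same stages
(`simulate / preprocess / select1 / select2 / train / evaluate / ablate
/ run`); `srpnet run` writes every artifact plus a manifest with content
hashes for reproducibility.

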