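# targetfish

Ligand-based target prediction ("target fishing") asks: given a small
molecule's chemical structure, which protein targets is it likely to be
active against? Most classifiers used for this task are *single-label*:
they assume each compound hits exactly one of the |L| candidate targets.
Real ligands are frequently promiscuous — one sixth of compounds in
curated bioactivity extracts are annotated against two or more targets —
so the single-target assumption throws information away.

`targetfish` implements and compares the two naive Bayes formulations of
the problem, together with the complete evaluation protocol needed to
decide between them, and a synthetic activity-data generator so that the
whole pipeline is testable without any external database. It is intended
for cheminformaticians studying multi-label classification of bioactivity
data, and as a reference implementation of the paired-model comparison
protocol.

## The models

A compound is a binary fingerprint **x** ∈ {0,1}^m (e.g. a folded
1,024-bit ECFP_4 vector). Bits are treated as conditionally independent
Bernoulli variables given the target class l, with Laplace-corrected
conditionals and maximum-likelihood priors estimated from an activity
dataset D = {(**x**_j, Y_j)}, Y_j ⊆ L:

    p(x_i = 1 | l) = (1 + n_il⁺) / (2 + n_l),      P(l) = n_l / N

**SMM — single-label multi-class model.** One shared-evidence classifier
over all |L| targets: the evidence p(**x**) sums the joint terms of every
class, so the posteriors p(l | **x**) form a softmax over classes and the
compound is assigned to the arg-max. SMM must be trained on single-label
data; a multi-label training set is first reduced by keeping, for each
compound, the target with the highest measured potency.

**MMM — multi-label multi-class model.** A binary-relevance
decomposition into |L| "pseudo single-label" classifiers H_l : χ → {l, ¬l}.
Each transformed dataset D_l keeps *all* N training instances, positive
iff the compound carries label l, with complementary priors n_l/N and
1 − n_l/N and a two-term evidence. The predicted label set is the union

    Z = ∪ { l : H_l(x) ≥ p_threshold }

with p_threshold tuned by stratified 5-fold cross-validation (default
grid includes 0.999). Because training compounds may themselves be
multi-label, the positives of different D_l overlap — H_l is not a
strict one-vs-all classifier.

All likelihood products are evaluated in log space (log-sum-exp /
stable logistic); with m = 1,024 the literal products underflow doubles.

## The evaluation protocol

* **Example-based recall/precision** for multi-label predictions: the
  means over test instances of |Y∩Z|/|Y| and |Y∩Z|/|Z|.
* **Per-class recall/precision** (TP/(TP+FN), TP/(TP+FP)) from *top-1*
  assignments on single-label test compounds, macro-averaged by default.
* **McNemar's test** (continuity-corrected χ² by default) on the
  discordant top-1 classifications of the two models.
* **Paired label-rank comparison**: both models rank all |L| posteriors
  for each multi-label test compound; the rank positions of every true
  label are paired across models (M = Σ|Y_t| pairs) and compared with a
  **Wilcoxon signed-rank test** (exact null enumeration for small
  samples, tie-corrected normal approximation otherwise).

## Worked example

```python
import numpy as np
import targetfish as tf
from targetfish.classifiers import train_mmm, train_smm, tune_threshold

cfg = tf.GeneratorConfig(seed=0)          # 20 targets, 2,000 compounds, 1,024 bits
data, truth = tf.generate_dataset(cfg)
train, test = tf.split_dataset(data, 0.7, seed=0)
train_single = tf.reduce_to_single_label(train)

smm = train_smm(train_single)
threshold = tune_threshold(train_single, folds=5, seed=0)
mmm = train_mmm(train, p_threshold=threshold)

single = test.subset(np.flatnonzero(~test.multi_label_mask()))
labels = data.label_space.labels
top = lambda model: [labels[k] for k in np.argmax(model.posterior_matrix(single.X), axis=1)]
rep_smm = tf.per_class_metrics(single.label_sets(), top(smm), data.label_space)
rep_mmm = tf.per_class_metrics(single.label_sets(), top(mmm), data.label_space)

multi = test.subset(np.flatnonzero(test.multi_label_mask()))
records, res = tf.paired_rank_comparison(
    smm.posterior_matrix(multi.X), mmm.posterior_matrix(multi.X), multi)
```

prints, with the accessors shown in `scripts/acceptance.py`:

```
tuned p_threshold = 0.5
SMM  recall 0.8267  precision 0.8360
MMM  recall 0.8384  precision 0.8590
paired positions M = 272: ties 151, SMM better 50, MMM better 71
mean true-label rank: SMM 3.438  MMM 3.235
Wilcoxon signed-rank p = 0.017 (favours MMM)
```

Reading the output: on the 500 single-label test compounds both models
assign the correct target to ~83% of compounds (macro-averaged top-1
recall). On the promiscuous test compounds, the 272 paired rank
positions of the true targets tie 151 times, but where the models
disagree the multi-label model places the true target nearer the top of
the ranking significantly more often — the promiscuity-aware
decomposition generalises better for promiscuous ligands, which is the
package's central comparison.

The same study runs from the shell:

```
targetfish simulate --scale tiny --seed 0 --out-dir fixture
targetfish run --simulate --seed 0 --out-dir run
```

`run/report.json` contains every metric block above plus the McNemar
comparison; reruns with the same seed are byte-identical.

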