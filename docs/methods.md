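# Methods

## Problem setting

An activity dataset is a bipartite relation between N compounds and a
fixed, ordered set L of protein targets. Compound j carries a length-m
binary fingerprint **x**_j (bit i encodes the presence of a circular
atom-environment descriptor), a non-empty label set Y_j ⊆ L of targets
it is active against, and optionally one potency value per
compound–target pair on a larger-is-more-potent scale (pIC50 by
convention here; a 1 µM cutoff corresponds to 6.0). The task is to learn
f : χ → Ω from annotated compounds and predict the target set of new
compounds. Ω is L itself for the single-label multi-class model (SMM)
and the power set of L for the multi-label multi-class model (MMM).

## Estimation

Both models are Bernoulli naive Bayes classifiers sharing the same
primitives:

* conditional on-probabilities with the Laplace correction,
  p(x_i=1 | l) = (1 + n_il⁺)/(2 + n_l). The 2 in the denominator
  reflects the two outcomes of a binary descriptor; an empty class gives
  exactly 1/2, and every estimate lies strictly inside (0, 1), so all
  log factors are finite. The factor for x_i = 0 is the Bernoulli
  complement 1 − p(x_i=1 | l).
* class priors P(l) = n_l/N (maximum likelihood); a class modeled by the
  SMM must be non-empty.

All products over the m bits are computed in log space. With m = 1,024
the direct product is ~e^(−700) and underflows double precision; the
implementation contract is *mathematical equality* with the product
form, enforced in the test suite by a brute-force product oracle at
m ≤ 20 (agreement to 1e-10 relative).

**SMM.** The evidence p(**x**) sums the |L| joint terms, so posteriors
are the softmax of the log-joints (log-sum-exp normalised; they sum to 1
within 1e-9). Prediction is the arg-max; the predicted set is always the
top singleton. SMM requires single-label training data and refuses
anything else, directing the caller to the reduction below.

**Single-label reduction.** A multi-label training compound is collapsed
onto the target with its highest measured potency. Equal potencies
resolve to the lowest label index — the ordering of L (lexicographic
unless supplied explicitly) is the single tie-break convention used
everywhere in the package, chosen because a deterministic artifact is
testable while "arbitrary" assignment is not. N never changes, and the
retained label always comes from the original Y.

**MMM.** Binary relevance: for every l the transformed dataset D_l keeps
all N instances, positive iff l ∈ Y_j. The positive block is fit on the
positives, the negative block on the rest, with complementary priors
n_l/N and 1 − n_l/N and the two-term evidence
p(**x**) = ∏p(x_i|l)P(l) + ∏p(x_i|¬l)P(¬l), i.e. a stable logistic of
the log-joint difference. A label with no negatives is a degenerate
binary problem and is rejected; a label with no positives is rejected by
default but can be explicitly allowed (it is then modeled with a zero
prior, so H_l ≡ 0 — the natural limit of the two-term evidence).
Prediction is the thresholded union Z = {l : H_l(x) ≥ p_threshold}; the
comparison is ≥, so boundary equality includes the label, p_threshold=0
yields Z = L, and Z(t₂) ⊆ Z(t₁) whenever t₂ ≥ t₁. The rank-1 label is
defined even when Z is empty so top-1 evaluation always applies.

**Threshold tuning.** p_threshold is chosen on a grid (default
{0.5, 0.9, 0.99, 0.995, 0.999, 0.9999}) by stratified k-fold
cross-validation (default 5 folds, stratified by each compound's
lowest-index label, fold assignment seeded). The objective is
example-based F1 on the held-out fold — the harmonic mean balances the
two metrics the protocol reports; precision-only and recall-only
objectives are selectable. Ties go to the larger threshold. If a
training fold loses a class, folds are redrawn once before failing.

## Evaluation protocol

* Example-based precision/recall: means over instances of |Y∩Z|/|Z| and
  |Y∩Z|/|Y|. An empty Z would divide by zero; such instances contribute
  0 to the precision mean and are counted rather than excluded, so |T|
  is stable. For all-singleton Y and Z both metrics reduce to top-1
  accuracy.
* Per-class precision/recall from top-1 assignments on single-label
  truth. Reported figures are macro-averages over labels with defined
  ratios; a label never predicted has undefined precision and is
  excluded and flagged (micro-averaging, which on single-label truth
  collapses both metrics to accuracy, is selectable). Macro is the
  default because reported single-label recall and precision generally
  differ, which micro-averaging cannot produce.
* McNemar's test on discordant top-1 classifications: default
  continuity-corrected χ² = (|b−c|−1)²/(b+c) on 1 df, applied literally
  (so (5,5) gives 0.1); uncorrected and exact-binomial variants are
  selectable since the literature rarely names the variant used. The
  favoured model is the one with fewer exclusive errors.
* Paired label-rank comparison: both models rank all |L| posteriors per
  multi-label test compound (descending, ties by label order); the
  positions of every true label are paired, M = Σ|Y_t| records. The
  Wilcoxon signed-rank test runs on the differences. If every difference
  is zero the result is flagged degenerate with p = 1 rather than
  raising.
* Wilcoxon signed-rank: statistic W⁺ (sum of average ranks of positive
  differences). Zeros are discarded before ranking by default (classic
  behaviour); the Pratt policy (rank with zeros, drop their ranks from
  the statistic) is selectable since zero-handling is often unstated in
  applications with many ties. The null is enumerated exactly for
  n_eff ≤ 25 by dynamic programming over doubled ranks (ties permitted);
  larger samples use the normal approximation with variance Σr_i²/4,
  which equals the textbook tie-corrected formula and handles Pratt
  zeros automatically. No continuity correction is applied, matching
  scipy's default so the two implementations can cross-check.

## Synthetic data generator

The generator emulates the statistical structure of a curated
bioactivity extract:

* **Promiscuity.** Label-set sizes are drawn from a distribution shaped
  like curated extracts: 83.1% single-label, 12.1% double, thinning to a
  pooled ~0.8% tail at size 10 (the tail of very promiscuous ligands).
  The label set itself is uniform without replacement.
* **Class profiles.** Each target has a Bernoulli profile: 16 signal
  bits at on-probability 0.30 over a 0.02 background, per-class signal
  sets sampled independently (they may overlap, as folded-fingerprint
  collisions and shared within-family pharmacophores do; a disjoint mode
  exists for clean didactic fixtures). The densities mimic folded
  1,024-bit ECFP vectors, which light up a few dozen bits. The
  signal/background contrast was calibrated once so that macro top-1
  assignment over 20 targets lands near 0.8 — the operating regime of
  published target-fishing benchmarks — rather than saturating at 1.0,
  where the two models become indistinguishable and the comparison
  protocol has nothing to detect.
* **Promiscuous fingerprints.** A compound's bits are drawn from the
  element-wise maximum of its targets' profiles, so a promiscuous
  compound genuinely resembles all of its targets — exactly the regime
  in which the single-label reduction discards information.
* **Potencies.** Independent Normal(7, 1) on the pIC50 scale per pair;
  only their ordering matters (it drives the single-label reduction).
* **Reproducibility.** All randomness flows from one seed through named
  SeedSequence sub-streams (profiles / membership / bits / potency), so
  each stage is independently reproducible and fixture bundles are
  byte-identical across reruns.

What the generator does *not* model: real chemistry (no SMILES, no
structural similarity beyond shared profile bits), assay noise and
confidence scores, correlated promiscuity (co-annotation is uniform
rather than family-structured), and class imbalance beyond what the
promiscuity draw induces. Passing tests on generated data therefore
demonstrate correctness of the estimators and protocol and the
direction of the single- vs multi-label comparison under the stated
generative assumptions — not performance on any particular real
database.

## Study sizes

The default desk-scale study uses 20 targets and 2,000 compounds
(~100 ligands per target, matching the 120–720-per-class window of
curated extracts at the low end). At this size the multi-label test
partition contains ~100 compounds and ~300 paired rank positions —
enough to see the direction of the comparison but underpowered for a
per-seed significance claim. The directional-replication test and the
acceptance script therefore scale the same study to 14,000 compounds,
which yields ~2,200 paired positions, a size at which the Wilcoxon
comparison resolves decisively seed after seed while the whole study
still runs in about a second. The null control (signal probability set
equal to the background, making classes indistinguishable) runs at the
2,000-compound scale and keeps the rejection rate at the nominal level.

## Known limitations

* The per-class macro averages are sensitive to very small classes; the
  micro option exists but conflates the two metrics on single-label
  truth.
* The exact Wilcoxon path is limited to n_eff ≤ 25 (DP over doubled
  ranks); beyond that the normal approximation is used, which is
  standard but approximate in the extreme tails.
* Binary relevance ignores label correlations by construction; no
  label-powerset or classifier-chain transformation is provided.
* The SMILES adapter produces RDKit Morgan fingerprints, which are a
  standard ECFP implementation but not bit-compatible with other
  toolkits' ECFP foldings.
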