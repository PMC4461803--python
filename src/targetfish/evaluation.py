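"""Evaluation schemes and paired statistical tests for the two models.

Two metric families are implemented:

* example-based recall/precision for multi-label predictions — the means
  over test instances of |Y ∩ Z| / |Y| and |Y ∩ Z| / |Z|;
* per-class recall/precision from top-1 assignments on single-label
  truth — TP / (TP + FN) and TP / (TP + FP) per label, macro- (default)
  or micro-averaged.

Model comparison follows the paired protocol: McNemar's test on the
discordant top-1 classifications of single-label test compounds, and a
Wilcoxon signed-rank test on the paired rank positions of the true
labels of multi-label test compounds (both models ranking all |L|
posteriors, the thresholded set playing no role).
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .classifiers import MultiLabelPrediction, rank_labels
from .data_io import ActivityDataset, DataError, LabelSpace

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "PairedRankRecord",
    "PairedTestResult",
    "example_based_metrics",
    "per_class_metrics",
    "top1_restrict",
    "rank_positions",
    "paired_rank_comparison",
    "mcnemar_test",
    "wilcoxon_signed_rank",
]


@dataclass
class EvalReport:
    """Precision/recall figures plus, for the per-class scheme, a per-label table."""

    scheme: str                    # "example_based" or "per_class"
    precision: float
    recall: float
    n_instances: int
    per_label: dict[str, dict] | None = None
    n_empty_predictions: int = 0
    undefined_precision_labels: tuple[str, ...] = ()
    undefined_recall_labels: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        out = {
            "scheme": self.scheme,
            "precision": self.precision,
            "recall": self.recall,
            "n_instances": self.n_instances,
            "n_empty_predictions": self.n_empty_predictions,
        }
        if self.per_label is not None:
            out["per_label"] = self.per_label
            out["undefined_precision_labels"] = list(self.undefined_precision_labels)
            out["undefined_recall_labels"] = list(self.undefined_recall_labels)
        return out


PairedRankRecord = namedtuple(
    "PairedRankRecord", ["compound_id", "label", "rank_a", "rank_b"]
)
PairedRankRecord.__doc__ = (
    "Rank position of one true label of one test compound under two models."
)


@dataclass
class PairedTestResult:
    """Outcome of a paired-classifier test (McNemar or Wilcoxon signed-rank)."""

    test_name: str
    statistic: float
    p_value: float
    n_effective: int
    direction: str                 # "a", "b" or "none"
    extras: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_effective": self.n_effective,
            "direction": self.direction,
            **self.extras,
        }


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def example_based_metrics(
    truth: Sequence[Iterable[str]], predicted: Sequence[Iterable[str]]
) -> EvalReport:
    """Example-based precision and recall over aligned truth/prediction sets.

    precision = mean_t |Y_t ∩ Z_t| / |Z_t|, recall = mean_t |Y_t ∩ Z_t| / |Y_t|.
    An instance with an empty predicted set contributes 0 to the precision
    mean (it is counted, not excluded, so |T| stays fixed) and is tallied
    in ``n_empty_predictions``.
    """
    if len(truth) != len(predicted):
        raise DataError("truth and prediction lists must be aligned")
    if len(truth) == 0:
        raise DataError("cannot evaluate an empty test set")
    prec_terms, rec_terms, n_empty = [], [], 0
    for Y, Z in zip(truth, predicted):
        Y, Z = set(Y), set(Z)
        if not Y:
            raise DataError("an instance with an empty truth set is not a valid annotation")
        inter = len(Y & Z)
        if Z:
            prec_terms.append(inter / len(Z))
        else:
            n_empty += 1
            prec_terms.append(0.0)
        rec_terms.append(inter / len(Y))
    if n_empty:
        logger.info("%d instances had empty predicted sets (precision term 0)", n_empty)
    return EvalReport(
        scheme="example_based",
        precision=float(np.mean(prec_terms)),
        recall=float(np.mean(rec_terms)),
        n_instances=len(truth),
        n_empty_predictions=n_empty,
    )


def per_class_metrics(
    truth: Sequence[Iterable[str]],
    predicted_top1: Sequence[str],
    label_space: LabelSpace,
    average: str = "macro",
) -> EvalReport:
    """Per-class precision/recall from top-1 assignments on single-label truth.

    TP for label A counts compounds of A assigned to A; FN counts
    compounds of A assigned elsewhere; FP counts compounds of other
    labels assigned to A. The reported figures are macro-averages over
    labels with defined ratios (a label never predicted has undefined
    precision and is excluded and flagged; likewise a label absent from
    the truth for recall). ``average="micro"`` pools the counts instead.
    """
    if len(truth) != len(predicted_top1):
        raise DataError("truth and prediction lists must be aligned")
    if len(truth) == 0:
        raise DataError("cannot evaluate an empty test set")
    if average not in ("macro", "micro"):
        raise DataError("average must be 'macro' or 'micro'")
    L = len(label_space)
    tp = np.zeros(L, dtype=np.int64)
    fp = np.zeros(L, dtype=np.int64)
    fn = np.zeros(L, dtype=np.int64)
    for Y, z in zip(truth, predicted_top1):
        Y = set(Y)
        if len(Y) != 1:
            raise DataError("per-class metrics require singleton truth sets")
        y = label_space.index(next(iter(Y)))
        k = label_space.index(z)  # raises for a prediction outside the label space
        if y == k:
            tp[y] += 1
        else:
            fn[y] += 1
            fp[k] += 1

    per_label: dict[str, dict] = {}
    undef_prec, undef_rec = [], []
    prec_vals, rec_vals = [], []
    for i, l in enumerate(label_space.labels):
        denom_p = tp[i] + fp[i]
        denom_r = tp[i] + fn[i]
        p = tp[i] / denom_p if denom_p else None
        r = tp[i] / denom_r if denom_r else None
        per_label[l] = {
            "TP": int(tp[i]), "FP": int(fp[i]), "FN": int(fn[i]),
            "precision": p, "recall": r,
        }
        if p is None:
            undef_prec.append(l)
        else:
            prec_vals.append(p)
        if r is None:
            undef_rec.append(l)
        else:
            rec_vals.append(r)
    if undef_prec:
        logger.info("labels never predicted (precision undefined): %s", undef_prec)

    if average == "micro":
        precision = float(tp.sum() / (tp.sum() + fp.sum()))
        recall = float(tp.sum() / (tp.sum() + fn.sum()))
    else:
        precision = float(np.mean(prec_vals)) if prec_vals else float("nan")
        recall = float(np.mean(rec_vals)) if rec_vals else float("nan")
    return EvalReport(
        scheme="per_class",
        precision=precision,
        recall=recall,
        n_instances=len(truth),
        per_label=per_label,
        undefined_precision_labels=tuple(undef_prec),
        undefined_recall_labels=tuple(undef_rec),
    )


def top1_restrict(pred: MultiLabelPrediction) -> frozenset[str]:
    """Singleton set holding the rank-1 label, ignoring p_threshold and Z."""
    return frozenset({pred.top_label})


def rank_positions(
    posterior_values, label_space: LabelSpace, true_labels: Iterable[str]
) -> list[int]:
    """1-based rank positions of the true labels in the descending-posterior order.

    Ties are deterministic: the lower label index outranks. The returned
    list follows label-space order over the true labels.
    """
    ranks = rank_labels(np.asarray(posterior_values, dtype=np.float64))
    idx = sorted(label_space.index(l) for l in set(true_labels))
    return [int(ranks[i]) for i in idx]


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

def mcnemar_test(
    only_a_wrong: int, only_b_wrong: int, variant: str = "continuity"
) -> PairedTestResult:
    """McNemar's test on the discordant pair counts of two classifiers.

    ``only_a_wrong`` (b) counts instances model A got wrong and model B
    right; ``only_b_wrong`` (c) the converse. The default statistic is
    the continuity-corrected chi-square (|b - c| - 1)^2 / (b + c) on one
    degree of freedom; ``variant="uncorrected"`` drops the correction and
    ``variant="exact"`` uses the two-sided binomial test. The favoured
    model is the one with fewer exclusive errors.
    """
    b, c = int(only_a_wrong), int(only_b_wrong)
    if b < 0 or c < 0:
        raise DataError("discordant counts must be non-negative")
    if b + c == 0:
        raise DataError("no discordant pairs")
    if variant == "continuity":
        statistic = (abs(b - c) - 1) ** 2 / (b + c)
        p = float(stats.chi2.sf(statistic, df=1))
    elif variant == "uncorrected":
        statistic = (b - c) ** 2 / (b + c)
        p = float(stats.chi2.sf(statistic, df=1))
    elif variant == "exact":
        statistic = float(min(b, c))
        p = float(stats.binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue)
    else:
        raise DataError(f"unknown McNemar variant {variant!r}")
    direction = "none" if b == c else ("a" if b < c else "b")
    return PairedTestResult(
        test_name="mcnemar",
        statistic=float(statistic),
        p_value=p,
        n_effective=b + c,
        direction=direction,
        extras={"only_a_wrong": b, "only_b_wrong": c, "variant": variant},
    )


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> tuple[float, float]:
    """Exact null tail probabilities of the signed-rank statistic.

    ``ranks2`` are the (average) ranks doubled so they are integers;
    ``w2`` is the doubled observed positive-rank sum. Returns
    (P(W+ <= w), P(W+ >= w)) by dynamic programming over the 2^n sign
    assignments (counts stay exact in doubles for n <= ~50).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = counts.sum()
    w2 = int(round(w2))
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return float(p_le), float(p_ge)


def wilcoxon_signed_rank(
    differences,
    zero_policy: str = "discard",
    mode: str = "auto",
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired differences.

    The statistic is W+, the sum of the (average, for tied magnitudes)
    ranks of the positive differences. Zeros are dropped before ranking
    under the classic ``discard`` policy, or ranked and then removed from
    the statistic under ``pratt``. The null distribution is enumerated
    exactly when the effective sample size is at most 25 (``mode="auto"``;
    force with ``"exact"``), otherwise a tie-corrected normal
    approximation is used. ``alternative="greater"`` tests for
    predominantly positive differences.

    All-zero input under the discard policy is a degenerate, not an
    error: the result carries p = 1 and a ``degenerate`` flag.
    """
    d = np.asarray(differences, dtype=np.float64)
    if d.size == 0:
        raise DataError("differences must be non-empty")
    if zero_policy not in ("discard", "pratt"):
        raise DataError("zero_policy must be 'discard' or 'pratt'")
    if alternative not in ("two-sided", "greater", "less"):
        raise DataError("alternative must be 'two-sided', 'greater' or 'less'")
    if mode not in ("auto", "exact", "normal_approx"):
        raise DataError("mode must be 'auto', 'exact' or 'normal_approx'")

    nonzero = d != 0
    n_eff = int(nonzero.sum())
    n_zero = int(d.size - n_eff)
    if n_eff == 0:
        return PairedTestResult(
            test_name="wilcoxon_signed_rank",
            statistic=0.0,
            p_value=1.0,
            n_effective=0,
            direction="none",
            extras={"degenerate": True, "n_zero": n_zero, "zero_policy": zero_policy},
        )

    if zero_policy == "discard":
        dd = d[nonzero]
        ranks = rankdata(np.abs(dd), method="average")
    else:  # pratt: rank with zeros in place, then drop the zero ranks
        ranks_all = rankdata(np.abs(d), method="average")
        dd = d[nonzero]
        ranks = ranks_all[nonzero]
    w_plus = float(ranks[dd > 0].sum())

    use_exact = mode == "exact" or (mode == "auto" and n_eff <= 25)
    if use_exact:
        p_le, p_ge = _signed_rank_exact_p(ranks * 2, w_plus * 2)
        method = "exact"
    else:
        mean = ranks.sum() / 2.0
        # variance of W+ under random signs: sum r_i^2 / 4 (absorbs ties & Pratt zeros)
        var = float((ranks ** 2).sum()) / 4.0
        if var == 0.0:
            p_le = p_ge = 1.0
        else:
            z = (w_plus - mean) / np.sqrt(var)
            p_ge = float(stats.norm.sf(z))
            p_le = float(stats.norm.cdf(z))
        method = "normal_approx"

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))

    n_pos = int((dd > 0).sum())
    n_neg = int((dd < 0).sum())
    direction = "none" if n_pos == n_neg else ("a" if n_pos > n_neg else "b")
    return PairedTestResult(
        test_name="wilcoxon_signed_rank",
        statistic=w_plus,
        p_value=p,
        n_effective=n_eff,
        direction=direction,
        extras={
            "degenerate": False,
            "method": method,
            "n_zero": n_zero,
            "zero_policy": zero_policy,
            "alternative": alternative,
        },
    )


def paired_rank_comparison(
    posteriors_a: np.ndarray,
    posteriors_b: np.ndarray,
    test: ActivityDataset,
    zero_policy: str = "discard",
    alternative: str = "two-sided",
) -> tuple[list[PairedRankRecord], PairedTestResult]:
    """Paired label-rank comparison of two models on a multi-label test set.

    For every test compound both models rank all |L| posteriors in
    descending order; the rank positions of each true label are paired,
    giving M = sum_t |Y_t| records. The Wilcoxon signed-rank test is run
    on the differences ``rank_a - rank_b`` (a positive difference means
    model B placed the true label better, i.e. nearer rank 1). Model B's
    posteriors must be computed with the threshold playing no role (the
    full ranking is used, as with p_threshold = 0).
    """
    A = np.asarray(posteriors_a, dtype=np.float64)
    B = np.asarray(posteriors_b, dtype=np.float64)
    if A.shape != (test.n, test.n_labels) or B.shape != (test.n, test.n_labels):
        raise DataError("posterior matrices must cover every test compound over the label space")

    records: list[PairedRankRecord] = []
    for i, cid in enumerate(test.compound_ids):
        ranks_a = rank_labels(A[i])
        ranks_b = rank_labels(B[i])
        for k in np.flatnonzero(test.Y[i]):
            records.append(
                PairedRankRecord(cid, test.label_space[k], int(ranks_a[k]), int(ranks_b[k]))
            )
    diffs = np.array([r.rank_a - r.rank_b for r in records], dtype=np.float64)
    ties = int((diffs == 0).sum())
    a_better = int((diffs < 0).sum())
    b_better = int((diffs > 0).sum())

    base = wilcoxon_signed_rank(diffs, zero_policy=zero_policy, alternative=alternative)
    direction = "none" if a_better == b_better else ("a" if a_better > b_better else "b")
    result = PairedTestResult(
        test_name="wilcoxon_signed_rank",
        statistic=base.statistic,
        p_value=base.p_value,
        n_effective=base.n_effective,
        direction=direction,
        extras={
            **base.extras,
            "M": len(records),
            "ties": ties,
            "a_better": a_better,
            "b_better": b_better,
            "mean_rank_a": float(np.mean([r.rank_a for r in records])),
            "mean_rank_b": float(np.mean([r.rank_b for r in records])),
        },
    )
    return records, result
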