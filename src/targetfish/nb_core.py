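"""Bernoulli naive Bayes primitives shared by both classifiers.

The model: a compound is a length-``m`` binary fingerprint ``x``; given a
class label ``l``, the bits are assumed independent Bernoulli variables
with on-probabilities ``p(x_i = 1 | l)``. Conditionals are estimated with
the Laplace correction ``(1 + n_on) / (2 + n_class)`` so they never touch
0 or 1, and class priors with the maximum-likelihood ratio
``n_class / n_total``.

All likelihood products are evaluated in log-space: with m ~ 1,024 bits
the literal per-bit product underflows double precision, so posteriors
are formed via log-sum-exp (shared-evidence mode) or a stable logistic
difference (binary l vs not-l mode). Mathematical equality with the
direct product is the contract, checked against a small-m brute-force
oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .data_io import DataError

__all__ = [
    "ClassCounts",
    "NBClassParams",
    "PosteriorVector",
    "estimate_conditional",
    "estimate_prior",
    "fit_class",
    "params_from_counts",
    "log_likelihood",
    "posterior_shared_evidence",
    "posterior_binary",
    "joint_log_likelihood",
]

#: modes a posterior vector can be in
SHARED_EVIDENCE = "shared_evidence"
PER_LABEL_BINARY = "per_label_binary"


@dataclass(frozen=True)
class ClassCounts:
    """Sufficient statistics of one class: instance count and per-bit on-counts."""

    n_class: int
    n_on: np.ndarray

    def __post_init__(self) -> None:
        n_on = np.asarray(self.n_on, dtype=np.int64)
        object.__setattr__(self, "n_on", n_on)
        if self.n_class < 0:
            raise DataError("negative class count")
        if (n_on < 0).any() or (n_on > self.n_class).any():
            raise DataError("corrupt counts: n_on outside [0, n_class]")


@dataclass(frozen=True)
class NBClassParams:
    """One class's prior and Laplace-smoothed per-bit on-probabilities."""

    prior: float
    cond_on: np.ndarray

    def __post_init__(self) -> None:
        cond = np.asarray(self.cond_on, dtype=np.float64)
        object.__setattr__(self, "cond_on", cond)
        if not 0.0 < self.prior <= 1.0:
            raise DataError(f"prior {self.prior} outside (0, 1]")
        if (cond <= 0.0).any() or (cond >= 1.0).any():
            raise DataError("conditional probabilities must lie strictly in (0, 1)")

    @property
    def m(self) -> int:
        return self.cond_on.shape[0]


@dataclass(frozen=True)
class PosteriorVector:
    """Per-label posteriors aligned to the label-space order.

    ``mode`` distinguishes shared-evidence posteriors (softmax over all
    classes; entries sum to 1) from per-label binary posteriors (each
    entry is an independent l vs not-l probability).
    """

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if self.mode not in (SHARED_EVIDENCE, PER_LABEL_BINARY):
            raise DataError(f"unknown posterior mode {self.mode!r}")
        if self.mode == SHARED_EVIDENCE and abs(vals.sum() - 1.0) > 1e-9:
            raise DataError("shared-evidence posterior does not sum to 1")


def estimate_conditional(n_on, n_class):
    """Laplace-corrected Bernoulli conditional ``(1 + n_on) / (2 + n_class)``.

    Accepts scalars or aligned arrays; with an empty class the estimate is
    exactly 1/2. The result always lies strictly inside (0, 1).
    """
    n_on = np.asarray(n_on)
    if (n_on < 0).any() or (n_on > n_class).any():
        raise DataError("corrupt counts: n_on outside [0, n_class]")
    out = (1.0 + n_on) / (2.0 + n_class)
    return float(out) if out.ndim == 0 else out


def estimate_prior(n_class: int, n_total: int) -> float:
    """Class prior ``n_class / n_total``; a modeled class must be non-empty."""
    if n_class < 1:
        raise DataError("cannot estimate a prior for an empty class")
    if n_class > n_total:
        raise DataError("class count exceeds total count")
    return n_class / n_total


def fit_class(instances, m: int | None = None) -> ClassCounts:
    """Count per-bit occurrences over the fingerprints of one class.

    ``instances`` is a sequence of equal-length binary vectors (or a 2-D
    array). An empty class is valid — Laplace smoothing absorbs it — but
    then ``m`` must be given explicitly.
    """
    try:
        X = np.asarray(list(instances) if not isinstance(instances, np.ndarray) else instances)
    except ValueError as exc:
        raise DataError("fingerprints must share a common length m") from exc
    if X.size == 0:
        if m is None:
            raise DataError("empty class: fingerprint length m must be supplied")
        return ClassCounts(n_class=0, n_on=np.zeros(m, dtype=np.int64))
    if X.ndim != 2:
        raise DataError("fingerprints must share a common length m")
    if m is not None and X.shape[1] != m:
        raise DataError("fingerprint length does not match requested m")
    if X.max(initial=0) > 1 or X.min(initial=0) < 0:
        raise DataError("non-binary fingerprint entry")
    return ClassCounts(n_class=X.shape[0], n_on=X.sum(axis=0).astype(np.int64))


def params_from_counts(counts: ClassCounts, prior: float) -> NBClassParams:
    """Turn sufficient statistics into smoothed parameters."""
    return NBClassParams(prior=prior, cond_on=estimate_conditional(counts.n_on, counts.n_class))


def log_likelihood(x, params: NBClassParams) -> float:
    """Log of ``P(l) * prod_i p(x_i | l)`` for one fingerprint.

    The x_i = 0 factor is the Bernoulli complement ``1 - p(x_i = 1 | l)``.
    Always finite because Laplace smoothing keeps every factor off {0, 1}.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != params.cond_on.shape:
        raise DataError("fingerprint length does not match parameter length")
    logp = np.log(params.cond_on)
    log1mp = np.log1p(-params.cond_on)
    return float(np.log(params.prior) + x @ (logp - log1mp) + log1mp.sum())


def joint_log_likelihood(X: np.ndarray, cond: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Batched log-joint ``log P(l) + sum_i log p(x_i | l)``.

    Parameters
    ----------
    X : (n, m) binary matrix
    cond : (L, m) matrix of on-probabilities
    priors : (L,) vector of class priors

    Returns an (n, L) matrix of log-joints.
    """
    X = np.asarray(X, dtype=np.float64)
    cond = np.asarray(cond, dtype=np.float64)
    if X.shape[1] != cond.shape[1]:
        raise DataError("fingerprint length does not match parameter length")
    logp = np.log(cond)
    log1mp = np.log1p(-cond)
    return X @ (logp - log1mp).T + log1mp.sum(axis=1) + np.log(priors)


def posterior_shared_evidence(x, all_params: list[NBClassParams]) -> PosteriorVector:
    """Multi-class posterior with the evidence summed over all |L| classes.

    ``p(x)`` is the sum of the |L| joint terms, so the result is the
    softmax of the log-joints (log-sum-exp normalised) and sums to 1.
    """
    if len(all_params) < 2:
        raise DataError("shared-evidence posterior needs at least two classes")
    ll = np.array([log_likelihood(x, p) for p in all_params])
    post = np.exp(ll - logsumexp(ll))
    post /= post.sum()  # clean residual rounding so the sum-to-1 contract holds
    return PosteriorVector(values=post, mode=SHARED_EVIDENCE)


def posterior_binary(x, pos: NBClassParams, neg: NBClassParams) -> float:
    """Binary l vs not-l posterior with the two-term evidence.

    ``p(x)`` is the sum of the joint terms of the positive (l) and
    negative (not-l) blocks, whose priors must be complementary
    (``n_l/N`` and ``1 - n_l/N``). Computed as a stable logistic of the
    log-joint difference; the result lies strictly in (0, 1).
    """
    if abs(pos.prior + neg.prior - 1.0) > 1e-9:
        raise DataError("positive and negative priors must sum to 1")
    return float(expit(log_likelihood(x, pos) - log_likelihood(x, neg)))
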