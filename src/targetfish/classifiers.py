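"""The two target-prediction models: SMM and MMM.

SMM (single-label multi-class model) is one shared-evidence Bernoulli
naive Bayes classifier over all |L| targets, trained on a single-label
dataset: each class block is fit on the compounds annotated against that
target only, priors are n_l / N, and a test compound is assigned the
class with the highest posterior.

MMM (multi-label multi-class model) decomposes the problem by binary
relevance into |L| "pseudo single-label" binary classifiers H_l: each
D_l keeps all N training instances, labelled positive iff the compound
carries label l. A compound's predicted label set is the union
Z = { l : H_l(x) >= p_threshold }, where H_l(x) is the binary posterior
with two-term evidence and complementary priors n_l/N and 1 - n_l/N.
Because training compounds may themselves be multi-label, the positives
of different D_l overlap — H_l is not a strict one-vs-all classifier.

p_threshold (0.999 by default) can be tuned by stratified k-fold
cross-validation on a grid of candidate values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from . import nb_core
from .data_io import ActivityDataset, DataError, LabelSpace
from .nb_core import PosteriorVector, joint_log_likelihood

__all__ = [
    "SMMModel",
    "MMMModel",
    "MultiLabelPrediction",
    "train_smm",
    "predict_smm",
    "train_mmm",
    "predict_mmm",
    "tune_threshold",
    "DEFAULT_THRESHOLD",
    "DEFAULT_THRESHOLD_GRID",
    "load_model",
]

#: posterior cutoff for membership in the predicted set Z
DEFAULT_THRESHOLD = 0.999
#: candidate grid for cross-validated threshold tuning
DEFAULT_THRESHOLD_GRID = (0.5, 0.9, 0.99, 0.995, 0.999, 0.9999)

_MODEL_FORMAT = "targetfish-model"
_MODEL_VERSION = 1


@dataclass(frozen=True)
class MultiLabelPrediction:
    """Per-label posteriors, the thresholded set Z, and rank positions.

    ``ranks[k]`` is the 1-based rank of label k when posteriors are
    sorted in descending order (ties resolved by label order, lowest
    index first). ``top_label`` is the rank-1 label and is defined even
    when Z is empty, so the top-1 evaluation rule always applies.
    """

    label_space: LabelSpace
    posterior: PosteriorVector
    Z: tuple[str, ...]
    top_label: str
    ranks: np.ndarray

    def rank_of(self, label: str) -> int:
        return int(self.ranks[self.label_space.index(label)])


def rank_labels(posterior_values: np.ndarray) -> np.ndarray:
    """1-based ranks of labels by descending posterior, ties by label index."""
    vals = np.asarray(posterior_values, dtype=np.float64)
    order = np.lexsort((np.arange(vals.shape[-1]), -vals))
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, vals.shape[-1] + 1)
    return ranks


def _prediction(label_space: LabelSpace, post: PosteriorVector, Z_mask: np.ndarray) -> MultiLabelPrediction:
    ranks = rank_labels(post.values)
    top = label_space[int(np.argmin(ranks))]
    Z = tuple(l for l, keep in zip(label_space.labels, Z_mask) if keep)
    return MultiLabelPrediction(label_space, post, Z, top, ranks)


# ---------------------------------------------------------------------------
# SMM
# ---------------------------------------------------------------------------

@dataclass
class SMMModel:
    """Shared-evidence multi-class naive Bayes over the full label space."""

    label_space: LabelSpace
    cond: np.ndarray          # (L, m) Laplace-smoothed on-probabilities
    priors: np.ndarray        # (L,) class priors, summing to 1
    N_train: int

    def __post_init__(self) -> None:
        self.cond = np.asarray(self.cond, dtype=np.float64)
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if self.cond.shape[0] != len(self.label_space) or self.priors.shape[0] != len(self.label_space):
            raise DataError("one parameter block per label is required")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise DataError("SMM priors must sum to 1")

    @property
    def m(self) -> int:
        return self.cond.shape[1]

    def posterior_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, L) shared-evidence posteriors for a batch of fingerprints."""
        jll = joint_log_likelihood(X, self.cond, self.priors)
        post = np.exp(jll - logsumexp(jll, axis=1, keepdims=True))
        return post / post.sum(axis=1, keepdims=True)

    def to_json(self) -> str:
        doc = {
            "format": _MODEL_FORMAT,
            "version": _MODEL_VERSION,
            "kind": "smm",
            "labels": list(self.label_space.labels),
            "m": self.m,
            "N_train": self.N_train,
            "priors": self.priors.tolist(),
            "cond": self.cond.tolist(),
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "SMMModel":
        doc = json.loads(text)
        if doc.get("format") != _MODEL_FORMAT or doc.get("kind") != "smm":
            raise DataError("not a serialized SMM model")
        return cls(
            label_space=LabelSpace(tuple(doc["labels"])),
            cond=np.array(doc["cond"]),
            priors=np.array(doc["priors"]),
            N_train=int(doc["N_train"]),
        )


def train_smm(d: ActivityDataset) -> SMMModel:
    """Fit the SMM on a single-label dataset.

    Each class block uses only the compounds annotated against that
    target; priors are n_l / N over the single-label training set.
    """
    if not d.is_single_label():
        raise DataError(
            "SMM requires a single-label training set; apply reduce_to_single_label first"
        )
    n_class = d.Y.sum(axis=0).astype(np.int64)
    if (n_class == 0).any():
        empty = [l for l, c in zip(d.label_space.labels, n_class) if c == 0]
        raise DataError(f"SMM requires every class non-empty; empty: {empty}")
    n_on = d.Y.T.astype(np.float64) @ d.X
    cond = (1.0 + n_on) / (2.0 + n_class[:, None])
    priors = n_class / d.n
    return SMMModel(d.label_space, cond, priors, N_train=d.n)


def predict_smm(model: SMMModel, x) -> MultiLabelPrediction:
    """Assign a compound to the class with the highest posterior.

    Z is always the singleton of the top label (single-label semantics);
    exact posterior ties resolve to the lowest label index.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != model.m:
        raise DataError("fingerprint length does not match model")
    post = model.posterior_matrix(x)[0]
    pv = PosteriorVector(values=post, mode=nb_core.SHARED_EVIDENCE)
    ranks = rank_labels(post)
    Z_mask = ranks == 1
    return _prediction(model.label_space, pv, Z_mask)


# ---------------------------------------------------------------------------
# MMM
# ---------------------------------------------------------------------------

@dataclass
class MMMModel:
    """|L| binary-relevance naive Bayes blocks with a union threshold rule."""

    label_space: LabelSpace
    pos_cond: np.ndarray      # (L, m) on-probabilities given l
    neg_cond: np.ndarray      # (L, m) on-probabilities given not-l
    n_pos: np.ndarray         # (L,) positive counts n_l
    N_train: int
    p_threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        self.pos_cond = np.asarray(self.pos_cond, dtype=np.float64)
        self.neg_cond = np.asarray(self.neg_cond, dtype=np.float64)
        self.n_pos = np.asarray(self.n_pos, dtype=np.int64)
        L = len(self.label_space)
        if self.pos_cond.shape[0] != L or self.neg_cond.shape[0] != L or self.n_pos.shape[0] != L:
            raise DataError("one l / not-l parameter pair per label is required")
        if not 0.0 <= self.p_threshold <= 1.0:
            raise DataError("p_threshold must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.pos_cond.shape[1]

    @property
    def pos_prior(self) -> np.ndarray:
        return self.n_pos / self.N_train

    def posterior_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n, L) per-label binary posteriors H_l(x) for a batch."""
        pos_prior = self.pos_prior
        with np.errstate(divide="ignore"):  # a zero prior (allowed-empty label) -> H_l = 0
            jll_pos = joint_log_likelihood(X, self.pos_cond, pos_prior)
            jll_neg = joint_log_likelihood(X, self.neg_cond, 1.0 - pos_prior)
        return expit(jll_pos - jll_neg)

    def to_json(self) -> str:
        doc = {
            "format": _MODEL_FORMAT,
            "version": _MODEL_VERSION,
            "kind": "mmm",
            "labels": list(self.label_space.labels),
            "m": self.m,
            "N_train": self.N_train,
            "n_pos": self.n_pos.tolist(),
            "p_threshold": self.p_threshold,
            "pos_cond": self.pos_cond.tolist(),
            "neg_cond": self.neg_cond.tolist(),
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "MMMModel":
        doc = json.loads(text)
        if doc.get("format") != _MODEL_FORMAT or doc.get("kind") != "mmm":
            raise DataError("not a serialized MMM model")
        return cls(
            label_space=LabelSpace(tuple(doc["labels"])),
            pos_cond=np.array(doc["pos_cond"]),
            neg_cond=np.array(doc["neg_cond"]),
            n_pos=np.array(doc["n_pos"]),
            N_train=int(doc["N_train"]),
            p_threshold=float(doc["p_threshold"]),
        )


def train_mmm(
    d: ActivityDataset,
    p_threshold: float = DEFAULT_THRESHOLD,
    allow_empty_labels: bool = False,
) -> MMMModel:
    """Fit the MMM by binary relevance on the full (multi-label) training set.

    For every label l the transformed dataset D_l keeps all N instances;
    the positive block is fit on compounds carrying l, the negative block
    on the rest, with complementary priors n_l/N and 1 - n_l/N. A label
    with no negatives is a degenerate binary problem and is rejected; a
    label with no positives is rejected unless ``allow_empty_labels``
    (Laplace smoothing keeps the empty block well-defined).
    """
    if not 0.0 <= p_threshold <= 1.0:
        raise DataError("p_threshold must lie in [0, 1]")
    n_pos = d.Y.sum(axis=0).astype(np.int64)
    if (n_pos == d.n).any():
        full = [l for l, c in zip(d.label_space.labels, n_pos) if c == d.n]
        raise DataError(f"labels with no negative instances: {full}")
    if (n_pos == 0).any():
        empty = [l for l, c in zip(d.label_space.labels, n_pos) if c == 0]
        if not allow_empty_labels:
            raise DataError(
                f"labels with no positive instances: {empty}; "
                "pass allow_empty_labels=True to keep them"
            )
        # a zero prior drives the positive joint to -inf, i.e. H_l(x) = 0
        # for every x; the conditionals themselves stay Laplace-smoothed
        warnings.warn(f"labels with no positive instances: {empty}", stacklevel=2)
    n_on_pos = d.Y.T.astype(np.float64) @ d.X
    n_on_all = d.X.sum(axis=0, dtype=np.float64)
    n_neg = d.n - n_pos
    pos_cond = (1.0 + n_on_pos) / (2.0 + n_pos[:, None])
    neg_cond = (1.0 + (n_on_all - n_on_pos)) / (2.0 + n_neg[:, None])
    return MMMModel(d.label_space, pos_cond, neg_cond, n_pos, d.n, p_threshold)


def predict_mmm(
    model: MMMModel, x, p_threshold_override: float | None = None
) -> MultiLabelPrediction:
    """Predict the thresholded union Z = { l : H_l(x) >= p_threshold }.

    Per-label posteriors are independent binary probabilities (they need
    not sum to 1). The comparison is >=, so boundary equality includes
    the label, and p_threshold = 0 yields Z = L. The rank-1 label is
    reported even when Z is empty.
    """
    t = model.p_threshold if p_threshold_override is None else p_threshold_override
    if not 0.0 <= t <= 1.0:
        raise DataError("p_threshold must lie in [0, 1]")
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != model.m:
        raise DataError("fingerprint length does not match model")
    post = model.posterior_matrix(x)[0]
    pv = PosteriorVector(values=post, mode=nb_core.PER_LABEL_BINARY)
    return _prediction(model.label_space, pv, post >= t)


# ---------------------------------------------------------------------------
# threshold tuning
# ---------------------------------------------------------------------------

def _stratified_folds(d: ActivityDataset, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by each compound's first (lowest-index) label."""
    strata = np.argmax(d.Y, axis=1)
    assignment = np.empty(d.n, dtype=np.intp)
    offset = 0
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        members = rng.permutation(members)
        assignment[members] = (np.arange(members.size) + offset) % folds
        offset += members.size  # rotate fold sizes across strata
    return assignment


def _example_f1(truth_Y: np.ndarray, Z_mask: np.ndarray) -> float:
    """Example-based F1 of a batch given boolean truth and prediction masks."""
    inter = (truth_Y & Z_mask).sum(axis=1)
    z_size = Z_mask.sum(axis=1)
    y_size = truth_Y.sum(axis=1)
    prec_terms = np.where(z_size > 0, inter / np.maximum(z_size, 1), 0.0)
    precision = float(prec_terms.mean())
    recall = float((inter / y_size).mean())
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


_OBJECTIVES = {"f1", "precision", "recall"}


def tune_threshold(
    train: ActivityDataset,
    folds: int = 5,
    grid=DEFAULT_THRESHOLD_GRID,
    objective: str = "f1",
    seed: int = 0,
) -> float:
    """Choose p_threshold by stratified k-fold cross-validation.

    For each fold an MMM is trained on the remaining data and scored on
    the held-out compounds; the grid value maximising the mean
    cross-validated objective (example-based F1 by default) is returned,
    with ties broken in favour of the larger threshold. Fold assignment
    is seeded; if a training fold loses a class entirely, folds are
    redrawn once before failing.
    """
    grid = sorted(set(float(t) for t in grid))
    if not grid:
        raise DataError("threshold grid must be non-empty")
    if any(t < 0.0 or t > 1.0 for t in grid):
        raise DataError("threshold grid values must lie in [0, 1]")
    if folds < 2:
        raise DataError("cross-validation needs at least two folds")
    if objective not in _OBJECTIVES:
        raise DataError(f"unknown objective {objective!r}; choose from {sorted(_OBJECTIVES)}")

    for attempt in range(2):
        rng = np.random.default_rng(seed + attempt)
        assignment = _stratified_folds(train, folds, rng)
        ok = all(
            train.Y[assignment != f].any(axis=0).all() for f in range(folds)
        )
        if ok:
            break
    else:
        raise DataError("a cross-validation fold left a class empty twice; use fewer folds")

    scores = np.zeros((folds, len(grid)))
    for f in range(folds):
        fit_idx = np.flatnonzero(assignment != f)
        held_idx = np.flatnonzero(assignment == f)
        model = train_mmm(train.subset(fit_idx))
        post = model.posterior_matrix(train.X[held_idx])
        truth = train.Y[held_idx]
        for g, t in enumerate(grid):
            Z_mask = post >= t
            inter = (truth & Z_mask).sum(axis=1)
            z_size = Z_mask.sum(axis=1)
            y_size = truth.sum(axis=1)
            prec = float(np.where(z_size > 0, inter / np.maximum(z_size, 1), 0.0).mean())
            rec = float((inter / y_size).mean())
            if objective == "precision":
                scores[f, g] = prec
            elif objective == "recall":
                scores[f, g] = rec
            else:
                scores[f, g] = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)

    means = scores.mean(axis=0)
    best = max(range(len(grid)), key=lambda g: (means[g], grid[g]))
    return grid[best]


def load_model(path):
    """Load a serialized model of either kind from a JSON file."""
    with open(path) as fh:
        text = fh.read()
    kind = json.loads(text).get("kind")
    if kind == "smm":
        return SMMModel.from_json(text)
    if kind == "mmm":
        return MMMModel.from_json(text)
    raise DataError(f"unknown model kind {kind!r}")
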