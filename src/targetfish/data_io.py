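"""Read, write and transform ligand-target activity datasets.

An activity dataset is a bipartite relation between compounds and protein
targets: each compound carries a fixed-length binary fingerprint, a set of
target labels it is active against, and (optionally) a potency value per
compound-target pair on a "larger is more potent" scale such as pIC50.

On-disk formats are plain text:

* activity triplets -- delimited rows ``compound_id, target_id, potency``,
  one row per ligand-target annotation;
* fingerprints -- a dense delimited 0/1 matrix with a leading
  ``compound_id`` column (or a ``SMILES<tab>compound_id`` file routed
  through the optional RDKit adapter);
* label groupings -- two columns ``target_id, group`` for protein-family
  style subsetting.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "LabelSpace",
    "ActivityDataset",
    "BinaryRelevanceDataset",
    "read_activity_triplets",
    "read_fingerprint_matrix",
    "fingerprints_from_smiles",
    "read_label_groups",
    "write_activity_triplets",
    "write_fingerprint_matrix",
    "filter_dataset",
    "reduce_to_single_label",
    "binary_relevance_transform",
    "split_dataset",
    "subset_labels",
]


class DataError(ValueError):
    """Raised when an input violates the dataset format contract."""


@dataclass(frozen=True)
class LabelSpace:
    """Ordered collection of unique target identifiers.

    The ordering is fixed and deterministic (lexicographic unless an
    explicit order is supplied) and defines all index and tie-break
    semantics downstream: posteriors are aligned to it, and every tied
    comparison resolves in favour of the lower label index.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise DataError("a label space needs at least two targets")
        if len(set(self.labels)) != len(self.labels):
            raise DataError("duplicate target identifiers in label space")
        object.__setattr__(self, "_lookup", {l: i for i, l in enumerate(self.labels)})

    @classmethod
    def from_iterable(cls, labels: Iterable[str], ordered: bool = False) -> "LabelSpace":
        """Build a label space, sorting lexicographically unless ``ordered``."""
        seq = list(labels)
        if not ordered:
            seq = sorted(set(seq))
        return cls(tuple(seq))

    def index(self, label: str) -> int:
        try:
            return self._lookup[label]  # type: ignore[attr-defined]
        except KeyError:
            raise DataError(f"unknown target {label!r}") from None

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self._lookup  # type: ignore[attr-defined]

    def __getitem__(self, i: int) -> str:
        return self.labels[i]


@dataclass
class ActivityDataset:
    """Compounds with binary fingerprints, label sets and pair potencies.

    Attributes
    ----------
    label_space : LabelSpace
        The fixed, ordered target vocabulary ``L``.
    compound_ids : list of str
        Unique compound identifiers, one per row.
    X : ndarray of uint8, shape (N, m)
        Binary fingerprint matrix.
    Y : ndarray of bool, shape (N, |L|)
        Annotation matrix; ``Y[j, k]`` is True iff compound ``j`` is
        active against label ``k``. Every row has at least one label.
    potency : ndarray of float, shape (N, |L|)
        Per-pair potency on a larger-is-more-potent scale (e.g. pIC50);
        NaN where unmeasured.
    """

    label_space: LabelSpace
    compound_ids: list[str]
    X: np.ndarray
    Y: np.ndarray
    potency: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.uint8)
        self.Y = np.ascontiguousarray(self.Y, dtype=bool)
        self.potency = np.ascontiguousarray(self.potency, dtype=np.float64)
        n = len(self.compound_ids)
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise DataError("fingerprint matrix shape does not match compound count")
        if self.Y.shape != (n, len(self.label_space)):
            raise DataError("annotation matrix shape does not match dataset")
        if self.potency.shape != self.Y.shape:
            raise DataError("potency matrix shape does not match annotation matrix")
        if n == 0:
            raise DataError("no annotations")
        if len(set(self.compound_ids)) != n:
            raise DataError("compound_ids are not unique")
        if self.X.max(initial=0) > 1:
            raise DataError("non-binary fingerprint entry")
        if not self.Y.any(axis=1).all():
            raise DataError("every compound must carry at least one label")

    # -- simple views ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.compound_ids)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def n_labels(self) -> int:
        return len(self.label_space)

    @property
    def n_pairs(self) -> int:
        """Total ligand-target pair count, sum_j |Y_j|."""
        return int(self.Y.sum())

    def label_sets(self) -> list[frozenset[str]]:
        labels = np.asarray(self.label_space.labels, dtype=object)
        return [frozenset(labels[row]) for row in self.Y]

    def multi_label_mask(self) -> np.ndarray:
        """Boolean mask of compounds annotated against two or more targets."""
        return self.Y.sum(axis=1) > 1

    def is_single_label(self) -> bool:
        return bool((self.Y.sum(axis=1) == 1).all())

    def subset(self, indices: Sequence[int]) -> "ActivityDataset":
        """Row subset sharing the full label space."""
        idx = np.asarray(indices, dtype=np.intp)
        return ActivityDataset(
            label_space=self.label_space,
            compound_ids=[self.compound_ids[i] for i in idx],
            X=self.X[idx],
            Y=self.Y[idx],
            potency=self.potency[idx],
        )


BinaryRelevanceDataset = namedtuple(
    "BinaryRelevanceDataset", ["label", "compound_ids", "X", "positive"]
)
BinaryRelevanceDataset.__doc__ = (
    "One-vs-rest view D_l of an activity dataset: every instance of D is "
    "kept, flagged positive iff the focal label is in its label set."
)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fingerprint_matrix(path, delimiter: str | None = None):
    """Read a dense 0/1 fingerprint matrix with a leading compound_id column.

    Returns ``(compound_ids, X)`` with ``X`` of dtype uint8.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if df.shape[1] < 2:
        raise DataError("fingerprint matrix needs a compound_id column and at least one bit")
    ids = df.iloc[:, 0].astype(str).tolist()
    bits = df.iloc[:, 1:].to_numpy()
    if not np.isin(bits, (0, 1)).all():
        raise DataError("non-binary fingerprint entry")
    return ids, bits.astype(np.uint8)


def fingerprints_from_smiles(path, m: int = 1024, radius: int = 2):
    """Fold Morgan/ECFP-style fingerprints from a ``SMILES<tab>compound_id`` file.

    Requires the optional RDKit dependency. Returns ``(compound_ids, X)``.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise DataError("SMILES input requires the optional rdkit dependency") from exc

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=m)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"malformed SMILES line {lineno}: expected 'SMILES<tab>id'")
            smiles, cid = parts
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise DataError(f"unparseable SMILES at line {lineno}: {smiles!r}")
            fp = gen.GetFingerprintAsNumPy(mol)
            ids.append(cid)
            rows.append(fp.astype(np.uint8))
    if not rows:
        raise DataError("empty SMILES file")
    return ids, np.vstack(rows)


def read_activity_triplets(
    triplets_path,
    fingerprint_source,
    *,
    smiles: bool = False,
    labels: Sequence[str] | None = None,
    delimiter: str | None = None,
    min_confidence: float | None = None,
    m: int = 1024,
) -> ActivityDataset:
    """Assemble an :class:`ActivityDataset` from a triplet file and fingerprints.

    The triplet file must have columns ``compound_id, target_id, potency``;
    an optional ``confidence`` column can be thresholded with
    ``min_confidence`` (a generic pre-filter; no database semantics are
    attached to it). Duplicate ``(compound, target)`` rows keep the highest
    potency. Compound order follows first appearance in the triplet file;
    the label space is the lexicographic union of target ids unless an
    explicit ordered ``labels`` list is supplied.
    """
    df = pd.read_csv(
        triplets_path, sep=delimiter, engine="python" if delimiter is None else "c",
        dtype=str,
    )
    required = {"compound_id", "target_id", "potency"}
    if not required.issubset(df.columns):
        raise DataError(f"triplet file must have columns {sorted(required)}")
    if df.empty:
        raise DataError("no annotations")

    def _to_float(s):
        # exact (correctly rounded) parse so write/read round-trips bit-for-bit
        if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    if min_confidence is not None:
        if "confidence" not in df.columns:
            raise DataError("min_confidence given but no 'confidence' column present")
        df = df[df["confidence"].map(_to_float) >= min_confidence]
        if df.empty:
            raise DataError("no annotations after confidence filter")

    df = df.copy()
    df["compound_id"] = df["compound_id"].astype(str)
    df["target_id"] = df["target_id"].astype(str)
    df["potency"] = df["potency"].map(_to_float)

    dup_mask = df.duplicated(subset=["compound_id", "target_id"], keep=False)
    if dup_mask.any():
        logger.warning(
            "%d duplicate (compound, target) rows; keeping highest potency",
            int(dup_mask.sum()),
        )

    if smiles:
        fp_ids, fp_X = fingerprints_from_smiles(fingerprint_source, m=m)
    else:
        fp_ids, fp_X = read_fingerprint_matrix(fingerprint_source, delimiter=delimiter)
    fp_lookup = {cid: i for i, cid in enumerate(fp_ids)}

    for rowno, cid in zip(df.index, df["compound_id"]):
        if cid not in fp_lookup:
            raise DataError(
                f"compound {cid!r} at triplet row {rowno + 2} has no fingerprint"
            )

    if labels is not None:
        space = LabelSpace.from_iterable(labels, ordered=True)
        stray = set(df["target_id"]) - set(space.labels)
        if stray:
            raise DataError(f"target ids outside the supplied label space: {sorted(stray)}")
    else:
        space = LabelSpace.from_iterable(df["target_id"])

    compound_order = list(dict.fromkeys(df["compound_id"]))
    cindex = {cid: i for i, cid in enumerate(compound_order)}
    n, L = len(compound_order), len(space)
    Y = np.zeros((n, L), dtype=bool)
    potency = np.full((n, L), np.nan)
    for cid, tid, pot in zip(df["compound_id"], df["target_id"], df["potency"]):
        i, k = cindex[cid], space.index(tid)
        Y[i, k] = True
        if np.isnan(potency[i, k]) or (not np.isnan(pot) and pot > potency[i, k]):
            potency[i, k] = pot

    X = fp_X[[fp_lookup[cid] for cid in compound_order]]
    return ActivityDataset(space, compound_order, X, Y, potency)


def write_activity_triplets(d: ActivityDataset, path, delimiter: str = ",") -> None:
    """Write one ``compound_id, target_id, potency`` row per annotated pair."""
    rows = []
    labels = d.label_space.labels
    for i, cid in enumerate(d.compound_ids):
        for k in np.flatnonzero(d.Y[i]):
            pot = d.potency[i, k]
            rows.append((cid, labels[k], "" if np.isnan(pot) else repr(float(pot))))
    df = pd.DataFrame(rows, columns=["compound_id", "target_id", "potency"])
    df.to_csv(path, sep=delimiter, index=False)


def write_fingerprint_matrix(d: ActivityDataset, path, delimiter: str = "\t") -> None:
    header = ["compound_id"] + [f"bit_{i}" for i in range(d.m)]
    df = pd.DataFrame(d.X, columns=header[1:])
    df.insert(0, "compound_id", d.compound_ids)
    df.to_csv(path, sep=delimiter, index=False)


def read_label_groups(path, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column ``target_id, group`` file into a mapping."""
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if not {"target_id", "group"}.issubset(df.columns):
        raise DataError("label grouping file must have columns target_id, group")
    return dict(zip(df["target_id"].astype(str), df["group"].astype(str)))


# ---------------------------------------------------------------------------
# dataset transformations
# ---------------------------------------------------------------------------

def filter_dataset(
    d: ActivityDataset,
    min_class_size: int = 120,
    max_class_size: int = 720,
    min_potency: float | None = 6.0,
) -> ActivityDataset:
    """Apply the potency cutoff and class-size window, once.

    Pairs whose measured potency falls below ``min_potency`` are removed
    first (pairs with no potency recorded are kept); then labels whose
    remaining ligand count falls outside ``[min_class_size,
    max_class_size]`` are dropped; finally compounds left with an empty
    label set are removed. The filter is deliberately applied a single
    time, not iterated to a fixed point.
    """
    if min_class_size > max_class_size:
        raise DataError("min_class_size must not exceed max_class_size")
    Y = d.Y.copy()
    potency = d.potency.copy()
    if min_potency is not None:
        weak = Y & ~np.isnan(potency) & (potency < min_potency)
        Y[weak] = False
        potency[~Y] = np.nan

    class_sizes = Y.sum(axis=0)
    keep_labels = (class_sizes >= min_class_size) & (class_sizes <= max_class_size)
    if not keep_labels.any():
        raise DataError("empty label space after filtering")
    if keep_labels.sum() < 2:
        raise DataError("fewer than two labels survive filtering")

    kept = [l for l, k in zip(d.label_space.labels, keep_labels) if k]
    space = LabelSpace(tuple(kept))
    Y = Y[:, keep_labels]
    potency = potency[:, keep_labels]
    keep_rows = Y.any(axis=1)
    if not keep_rows.any():
        raise DataError("no compounds survive filtering")
    idx = np.flatnonzero(keep_rows)
    return ActivityDataset(
        space,
        [d.compound_ids[i] for i in idx],
        d.X[idx],
        Y[idx],
        potency[idx],
    )


def reduce_to_single_label(d: ActivityDataset) -> ActivityDataset:
    """Collapse every multi-label compound onto its highest-potency target.

    Each output annotation has exactly one label: the argmax of the
    compound's potencies over its label set, with ties broken by label
    order (lowest index wins). Single-label compounds pass through
    unchanged. N never changes and no label outside the original Y is
    introduced.
    """
    Y = d.Y.copy()
    multi = np.flatnonzero(d.Y.sum(axis=1) > 1)
    for i in multi:
        members = np.flatnonzero(d.Y[i])
        vals = d.potency[i, members]
        if np.isnan(vals).any():
            raise DataError(
                f"compound {d.compound_ids[i]!r} is multi-label but lacks a potency "
                "for one of its targets; cannot reduce to single label"
            )
        best = members[int(np.argmax(vals))]  # argmax takes the first (lowest-index) max
        Y[i, :] = False
        Y[i, best] = True
    return ActivityDataset(d.label_space, list(d.compound_ids), d.X, Y, d.potency)


def binary_relevance_transform(d: ActivityDataset, label: str) -> BinaryRelevanceDataset:
    """Build the binary-relevance dataset D_l for one label.

    D_l contains *all* N instances of ``d``; an instance is positive iff
    ``label`` is in its label set, negative otherwise. No instance is
    dropped, so a promiscuous compound is positive in every D_l of its
    targets and negative everywhere else.
    """
    k = d.label_space.index(label)
    return BinaryRelevanceDataset(
        label=label,
        compound_ids=list(d.compound_ids),
        X=d.X,
        positive=d.Y[:, k].copy(),
    )


def split_dataset(
    d: ActivityDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[ActivityDataset, ActivityDataset]:
    """Random, reproducible compound-level split into train and test.

    ``|train| = round(train_fraction * N)``; both halves share the full
    label space, and the partition is disjoint by compound_id.
    """
    if not 0.0 < train_fraction < 1.0:
        raise DataError("train_fraction must lie strictly between 0 and 1")
    if d.n < 2:
        raise DataError("cannot split a dataset with fewer than two compounds")
    n_train = int(round(train_fraction * d.n))
    n_train = min(max(n_train, 1), d.n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(d.n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return d.subset(train_idx), d.subset(test_idx)


def subset_labels(d: ActivityDataset, keep: Iterable[str]) -> ActivityDataset:
    """Restrict the dataset to a subset of labels (e.g. one protein family).

    Labels keep their original relative order; compounds whose label set
    becomes empty are dropped.
    """
    keep_set = set(keep)
    stray = keep_set - set(d.label_space.labels)
    if stray:
        raise DataError(f"labels not in dataset: {sorted(stray)}")
    mask = np.array([l in keep_set for l in d.label_space.labels])
    if mask.sum() < 2:
        raise DataError("a label subset needs at least two targets")
    space = LabelSpace(tuple(l for l, k in zip(d.label_space.labels, mask) if k))
    Y = d.Y[:, mask]
    rows = np.flatnonzero(Y.any(axis=1))
    if rows.size == 0:
        raise DataError("no compounds annotated against the requested labels")
    return ActivityDataset(
        space,
        [d.compound_ids[i] for i in rows],
        d.X[rows],
        Y[rows],
        d.potency[rows][:, mask],
    )
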