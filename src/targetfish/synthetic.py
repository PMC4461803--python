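"""Synthetic bipartite ligand-target activity data.

The generator emulates the statistical structure the classifiers assume:
each target class has a Bernoulli bit profile (a small set of "signal"
bits elevated above a sparse background), a compound draws its label-set
size from a promiscuity distribution shaped like curated bioactivity
extracts (~83% single-label, ~12% two-label, a thin tail of highly
promiscuous ligands), picks that many targets uniformly, and then draws
its fingerprint bit-wise from the element-wise maximum of its targets'
profiles — so a promiscuous compound genuinely resembles every one of
its targets. Potencies are independent normals on the pIC50 scale; only
their ordering matters (for the single-label reduction).

All randomness flows from one seed through named sub-streams (profiles,
membership, bits, potency, split) so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import (
    ActivityDataset,
    DataError,
    LabelSpace,
    split_dataset,
    write_activity_triplets,
    write_fingerprint_matrix,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "TABLE_PROMISCUITY",
    "generate_profiles",
    "generate_dataset",
    "make_benchmark_fixture",
]

#: default promiscuity distribution: fraction of compounds per label-set
#: size, shaped like a curated ChEMBL-style extract (83.1% single-label,
#: 16.9% annotated against two or more targets; the >=10 tail is pooled
#: at size 10). Normalised at use.
TABLE_PROMISCUITY: dict[int, float] = {
    1: 0.831, 2: 0.121, 3: 0.0239, 4: 0.0049, 5: 0.0036,
    6: 0.0029, 7: 0.0020, 8: 0.0009, 9: 0.0006, 10: 0.0080,
}

_STREAMS = {"profiles": 0, "membership": 1, "bits": 2, "potency": 3, "split": 4}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic activity-data generator.

    Defaults describe the desk-scale study: 20 targets, 1,024-bit sparse
    fingerprints, 2,000 compounds, the pooled promiscuity distribution
    above, 16 signal bits per class at on-probability 0.30 over a 0.02
    background, signal sets sampled independently per class (so related
    classes may share bits, as folded circular fingerprints and
    within-family pharmacophores do). The densities mimic folded ECFP
    vectors, which light up a few dozen of 1,024 bits, and the
    signal-to-background contrast is calibrated so top-1 assignment over
    the label space is challenging but clearly better than chance —
    the operating regime of published target-fishing benchmarks — rather
    than saturated. Pair potencies are Normal(7, 1) on the pIC50 scale.
    """

    n_labels: int = 20
    m: int = 1024
    n_compounds: int = 2000
    promiscuity: dict[int, float] = field(default_factory=lambda: dict(TABLE_PROMISCUITY))
    signal_bits_per_class: int = 16
    signal_on_prob: float = 0.30
    background_on_prob: float = 0.02
    disjoint_signal: bool = False
    potency_mean: float = 7.0
    potency_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_labels < 2 or self.m < 1 or self.n_compounds < 1:
            raise DataError("n_labels, m and n_compounds must be positive (n_labels >= 2)")
        if not self.promiscuity:
            raise DataError("promiscuity distribution must be non-empty")
        probs = np.array(list(self.promiscuity.values()), dtype=np.float64)
        sizes = np.array(list(self.promiscuity.keys()), dtype=np.int64)
        if (probs < 0).any() or probs.sum() <= 0:
            raise DataError("promiscuity probabilities must be non-negative and sum > 0")
        if (sizes[probs > 0] > self.n_labels).any():
            raise DataError("a label-set size with positive probability exceeds n_labels")
        for p in (self.signal_on_prob, self.background_on_prob):
            if not 0.0 < p < 1.0:
                raise DataError("on-probabilities must lie strictly in (0, 1)")
        if self.disjoint_signal and self.signal_bits_per_class * self.n_labels > self.m:
            raise DataError(
                "disjoint signal bits do not fit: signal_bits_per_class * n_labels > m"
            )
        if self.potency_sd <= 0:
            raise DataError("potency_sd must be positive")

    def normalized_promiscuity(self) -> tuple[np.ndarray, np.ndarray]:
        sizes = np.array(sorted(self.promiscuity), dtype=np.int64)
        probs = np.array([self.promiscuity[int(s)] for s in sizes], dtype=np.float64)
        return sizes, probs / probs.sum()


@dataclass
class GroundTruth:
    """What the generator actually drew: class profiles and the config echo."""

    profiles: np.ndarray          # (n_labels, m) true Bernoulli on-probabilities
    labels: tuple[str, ...]
    config: GeneratorConfig

    def to_json(self) -> str:
        doc = {
            "labels": list(self.labels),
            "profiles": np.asarray(self.profiles).tolist(),
            "config": {**asdict(self.config),
                       "promiscuity": {str(k): v for k, v in self.config.promiscuity.items()}},
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def _label_names(n: int) -> tuple[str, ...]:
    return tuple(f"T{i:03d}" for i in range(n))


def generate_profiles(cfg: GeneratorConfig) -> np.ndarray:
    """Draw per-class Bernoulli profiles, deterministic from the seed.

    Each class receives ``signal_bits_per_class`` bits at the elevated
    on-probability; every other bit sits at the background rate. With
    ``disjoint_signal`` the signal sets are non-overlapping slices of a
    seeded permutation of the bit positions; otherwise each class samples
    its signal bits independently (they may overlap).
    """
    cfg.validate()
    rng = _stream(cfg.seed, "profiles")
    profiles = np.full((cfg.n_labels, cfg.m), cfg.background_on_prob)
    k = cfg.signal_bits_per_class
    if cfg.disjoint_signal:
        perm = rng.permutation(cfg.m)
        for c in range(cfg.n_labels):
            profiles[c, perm[c * k:(c + 1) * k]] = cfg.signal_on_prob
    else:
        for c in range(cfg.n_labels):
            profiles[c, rng.choice(cfg.m, size=k, replace=False)] = cfg.signal_on_prob
    return profiles


def generate_dataset(cfg: GeneratorConfig) -> tuple[ActivityDataset, GroundTruth]:
    """Generate a full activity dataset plus its ground truth.

    Each compound draws |Y| from the promiscuity distribution, then Y
    uniformly without replacement; fingerprint bits come from the
    element-wise maximum of its classes' profiles; potencies are drawn
    per annotated pair.
    """
    cfg.validate()
    profiles = generate_profiles(cfg)
    labels = _label_names(cfg.n_labels)
    space = LabelSpace(labels)

    rng_mem = _stream(cfg.seed, "membership")
    sizes, probs = cfg.normalized_promiscuity()
    set_sizes = rng_mem.choice(sizes, size=cfg.n_compounds, p=probs)
    if (set_sizes > cfg.n_labels).any():
        raise DataError("drawn label-set size exceeds the number of labels")
    # uniform label subsets: take the k smallest entries of a random row
    R = rng_mem.random((cfg.n_compounds, cfg.n_labels))
    order = np.argsort(R, axis=1)
    Y = np.zeros((cfg.n_compounds, cfg.n_labels), dtype=bool)
    for i, k in enumerate(set_sizes):
        Y[i, order[i, :k]] = True

    rng_bits = _stream(cfg.seed, "bits")
    eff = np.empty((cfg.n_compounds, cfg.m))
    for i in range(cfg.n_compounds):
        eff[i] = profiles[Y[i]].max(axis=0)
    X = (rng_bits.random((cfg.n_compounds, cfg.m)) < eff).astype(np.uint8)

    rng_pot = _stream(cfg.seed, "potency")
    potency = np.full((cfg.n_compounds, cfg.n_labels), np.nan)
    n_pairs = int(Y.sum())
    potency[Y] = rng_pot.normal(cfg.potency_mean, cfg.potency_sd, size=n_pairs)

    ids = [f"C{i:06d}" for i in range(cfg.n_compounds)]
    dataset = ActivityDataset(space, ids, X, Y, potency)
    return dataset, GroundTruth(profiles=profiles, labels=labels, config=cfg)


_SCALES = {
    # 20 targets x ~100 compounds each; end-to-end in well under a minute
    "tiny": dict(n_labels=20, n_compounds=2000, m=1024),
    # the full label-space width at a desk-scale compound count
    "full": dict(n_labels=308, n_compounds=20000, m=1024),
}


def make_benchmark_fixture(scale: str = "tiny", seed: int = 0, out_dir=".") -> dict[str, str]:
    """Emit a complete fixture bundle in the package's own text formats.

    Writes activity triplets, the fingerprint matrix, a ground-truth JSON
    sidecar, a label-grouping file (four synthetic families assigned
    round-robin), and a 70/30 split manifest. Re-running with the same
    seed reproduces the files byte for byte. Returns the path of each
    artifact.
    """
    if scale not in _SCALES:
        raise DataError(f"unknown scale {scale!r}; choose from {sorted(_SCALES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=seed, **_SCALES[scale])
    dataset, truth = generate_dataset(cfg)
    train, test = split_dataset(dataset, train_fraction=0.7, seed=cfg.seed)

    paths = {
        "triplets": str(out / "triplets.csv"),
        "fingerprints": str(out / "fingerprints.tsv"),
        "groups": str(out / "label_groups.csv"),
        "ground_truth": str(out / "ground_truth.json"),
        "split": str(out / "split_manifest.json"),
    }
    write_activity_triplets(dataset, paths["triplets"])
    write_fingerprint_matrix(dataset, paths["fingerprints"])
    families = ("enzyme", "membrane_receptor", "ion_channel", "transporter")
    with open(paths["groups"], "w") as fh:
        fh.write("target_id,group\n")
        for i, l in enumerate(truth.labels):
            fh.write(f"{l},{families[i % len(families)]}\n")
    with open(paths["ground_truth"], "w") as fh:
        fh.write(truth.to_json())
    manifest = {
        "scale": scale,
        "seed": seed,
        "train_fraction": 0.7,
        "train_ids": list(train.compound_ids),
        "test_ids": list(test.compound_ids),
    }
    with open(paths["split"], "w") as fh:
        json.dump(manifest, fh, sort_keys=True, separators=(",", ":"))
    return paths
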