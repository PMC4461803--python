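import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from targetfish import ActivityDataset, GeneratorConfig, LabelSpace, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_dataset() -> ActivityDataset:
    """Two classes, two bits: the hand-checkable naive Bayes example.

    Class A holds fingerprints (1,0) and (1,1); class B holds (0,1) twice.
    Laplace gives cond(A) = (0.75, 0.5), cond(B) = (0.25, 0.75), priors
    (0.5, 0.5), and the query (1,0) has posterior(A) = 6/7.
    """
    space = LabelSpace(("A", "B"))
    X = np.array([[1, 0], [1, 1], [0, 1], [0, 1]], dtype=np.uint8)
    Y = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=bool)
    pot = np.where(Y, 7.0, np.nan)
    return ActivityDataset(space, ["c1", "c2", "c3", "c4"], X, Y, pot)


@pytest.fixture(scope="session")
def tiny_dataset() -> ActivityDataset:
    """A small but non-trivial generated dataset shared across tests."""
    cfg = GeneratorConfig(
        n_labels=8,
        m=128,
        n_compounds=600,
        signal_bits_per_class=8,
        promiscuity={1: 0.80, 2: 0.14, 3: 0.04, 4: 0.02},
        seed=7,
    )
    dataset, _ = generate_dataset(cfg)
    return dataset
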