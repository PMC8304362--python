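import numpy as np
import pytest

import redinfo as ri


@pytest.fixture(scope="session")
def canonical_pmfs():
    return {t: ri.make_canonical(t) for t in ri.CANONICAL_TASKS}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def one_hot_dataset(n, n_classes, seed, duplicate=2):
    """Dataset whose sources are identical one-hot encodings of the label."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, size=n)
    X = np.eye(n_classes)[y]
    return ri.LabeledDataset([X.copy() for _ in range(duplicate)], y, n_classes)


def independent_dataset(n, n_classes, n_features, seed, n_sources=2):
    """Sources carrying no information about the label."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, size=n)
    Xs = [rng.standard_normal((n, n_features)) for _ in range(n_sources)]
    return ri.LabeledDataset(Xs, y, n_classes)


# fast optimisation settings for unit tests (small data, short training)
FAST = dict(epochs=30, batch_size=128)
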