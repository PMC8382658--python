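import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_blobs(n_per, centers, sd, seed):
    """Isotropic Gaussian blobs; returns (X, labels 1-based)."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    X = np.vstack(
        [c + rng.normal(0, sd, size=(n_per, centers.shape[1])) for c in centers]
    )
    labels = np.repeat(np.arange(1, len(centers) + 1), n_per)
    return X, labels


@pytest.fixture
def four_blobs():
    centers = np.array(
        [[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8]], dtype=float
    )
    return make_blobs(120, centers, sd=0.6, seed=7)
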