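import numpy as np
import pytest

from spectrumclust import gaussian_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def points8(rng):
    """Eight generic 2-D points (no ties in any pairwise distance)."""
    return rng.normal(size=(8, 2))


@pytest.fixture
def blobs3():
    """Three well-separated Gaussian blobs, 30 points each."""
    return gaussian_blobs(K=3, n_per=30, dims=2, separation=14.0, sd=1.0, seed=7)
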