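import numpy as np
import pytest

from skinmesh.skinmodel import GMMParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separated_mixture():
    """Two equal-weight unit-covariance components 5σ apart."""
    return GMMParams(
        priors=[0.5, 0.5],
        means=[[0.0, 0.0], [5.0, 5.0]],
        covariances=[np.eye(2), np.eye(2)],
    )


@pytest.fixture
def random_rgb(rng):
    return rng.random((12, 17, 3))
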