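import numpy as np
import pytest

from fibermap import ParametricMap, gaussianize, learn_model, simulate_grf


@pytest.fixture(scope="session")
def grf_batch():
    """Ten 256x256 unit-variance GRF realizations (kernel width 3)."""
    return [simulate_grf((256, 256), 3.0, 1.0, seed=s) for s in range(10)]


@pytest.fixture(scope="session")
def grf_model(grf_batch):
    """GRF model learned from the gaussianized batch."""
    return learn_model([gaussianize(ParametricMap(s.image)) for s in grf_batch])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
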