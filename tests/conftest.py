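import numpy as np
import pytest

from ptsflux import branch
from ptsflux.synth import make_toy_network


@pytest.fixture(scope="session")
def calibrated_params():
    """Shipped default parameter set (printed K's, calibrated velocity scale)."""
    return branch.calibrated_parameters()


@pytest.fixture(scope="session")
def toy_network():
    return make_toy_network()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
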