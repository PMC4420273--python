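import numpy as np
import pytest

from bulbnet.network import aggregate_singles, build_network


@pytest.fixture(scope="session")
def default_net():
    """One aggregated 3-glomerulus default network, shared across tests."""
    return aggregate_singles(build_network("default", 2, seed=0))


@pytest.fixture(scope="session")
def two_cell_net():
    """Small two-mitral default network (B super-inhibits A)."""
    return aggregate_singles(build_network("default", 1, seed=0,
                                           separation=400.0, two_cell=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
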