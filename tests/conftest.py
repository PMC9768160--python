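import numpy as np
import pytest

from satnet import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A network small enough for exhaustive cross-checks.

    tau2 is raised so that short horizons still contain plenty of
    update events.
    """
    return NetworkConfig(N=24, n=6, tau2=0.05)


@pytest.fixture
def default_config():
    return NetworkConfig()
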