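import numpy as np
import pytest

import metaplast as mp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params(rng):
    """A small random network for mechanics tests."""
    return mp.init_params(20, rng)


@pytest.fixture
def tiny_episode(rng):
    return mp.make_episode(4, rng)


@pytest.fixture(scope="session")
def planted():
    """Planted 8-item network with linearly spaced probe alignments."""
    from metaplast.cli_io import make_planted_network
    rng = np.random.default_rng(777)
    targets = np.linspace(0.8, -0.8, 8)
    return make_planted_network(8, targets, rng)
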