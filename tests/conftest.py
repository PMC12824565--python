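import numpy as np
import pytest

from fretspt.simulate import SimulationConfig, simulate_movie


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured movie configuration."""
    return SimulationConfig(field_size=(96, 96), n_frames=120, seed=7)


@pytest.fixture(scope="session")
def small_movie(small_config):
    """One rendered movie plus its ground truth (shared across tests)."""
    return simulate_movie(small_config)
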