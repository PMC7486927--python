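import numpy as np
import pytest

from autoreservoir import LorenzConfig, simulate_coupled_lorenz


@pytest.fixture(scope="session")
def lorenz_small():
    """One 90-variable trajectory, 120 samples, reused across tests."""
    return simulate_coupled_lorenz(LorenzConfig(n_samples=120, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
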