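import numpy as np
import pytest

from tendomics.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A compact synthetic study shared by read-only tests."""
    cfg = SimulationConfig(seed=42, n_genes=150, n_peaks=120)
    return simulate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
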