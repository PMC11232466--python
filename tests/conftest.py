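import numpy as np
import pytest

from lderge.simulate import SimulationConfig, make_synthetic_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario kept small for unit tests: 10 AR(1) blocks of 50."""
    return SimulationConfig(n=800, m=500, block_size=50, replicates=2, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, X = make_synthetic_panel(
        small_config, np.random.default_rng(small_config.seed), return_genotypes=True
    )
    return panel, X
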