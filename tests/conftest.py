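import numpy as np
import pytest

from tautrace import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A quick-to-render single-well condition used by several suites."""
    return SimulationConfig(
        n_wells=1,
        n_cells_per_well=15,
        image_size_px=160,
        frames=40,
        rng_seed=17,
        onset_base_hazard_per_h=0.01,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
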