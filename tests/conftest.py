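import numpy as np
import pytest

from paleoks.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated 5-species dataset with a WGD planted at 75 Mya."""
    return simulate_dataset(SimulationConfig(seed=7, n_base_genes=60))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
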