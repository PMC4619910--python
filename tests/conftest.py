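import numpy as np
import pytest
from hypothesis import settings

from coexmir.simulate import SimulationConfig, simulate

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast-but-complete synthetic study: cliques, DE genes, planted sites."""
    return SimulationConfig(n_genes=120, utr_length_range=(80, 140), rng_seed=0)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(matrix, utr_records, truth) for the small synthetic study."""
    return simulate(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
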