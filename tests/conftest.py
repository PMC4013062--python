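import numpy as np
import pytest

from afnet.config import SimulationConfig
from afnet.simulate import simulate_cohort, simulate_gene_sets, simulate_network


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A fast, down-scaled cohort for unit tests."""
    return SimulationConfig(
        n_samples=400, n_families=120, n_genes=60, n_signal_genes=12,
        planted_module_size=6, n_gene_sets=20, gene_set_size_range=(5, 15),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_network(small_cfg, small_cohort):
    _, _, signal = small_cohort
    return simulate_network(small_cfg, signal)


@pytest.fixture(scope="session")
def small_gene_sets(small_cfg, small_network):
    _, planted = small_network
    return simulate_gene_sets(small_cfg, planted)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
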