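import numpy as np
import pytest

from tubertrace import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Study-default simulation, shared across tests (read-only)."""
    return simulate_dataset(SimulationConfig(rng_seed=42))


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down simulation for fast structural tests."""
    cfg = SimulationConfig(
        seed_richness_flesh=40,
        seed_richness_peel=60,
        horizontal_pool_size={
            ("daughter", "flesh", "Brunswick"): 50,
            ("daughter", "peel", "Brunswick"): 90,
            ("granddaughter", "flesh", "Brunswick"): 70,
            ("granddaughter", "peel", "Brunswick"): 150,
            ("granddaughter", "tare_soil", "Brunswick"): 200,
            ("granddaughter", "flesh", "Murdoch"): 70,
            ("granddaughter", "peel", "Murdoch"): 150,
            ("granddaughter", "tare_soil", "Murdoch"): 200,
        },
        n_replicates=4,
        rng_seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
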