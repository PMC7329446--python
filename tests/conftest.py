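import numpy as np
import pytest

from stratascan import sim


@pytest.fixture(scope="session")
def small_config():
    """A small but signal-bearing genome for fast unit tests."""
    return sim.SimulationConfig(
        n_autosomal_scaffolds=6,
        scaffold_length=150_000,
        n_par=1,
        n_stratum1=1,
        n_stratum2=1,
        n_w_specific=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return sim.simulate_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
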