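import pytest

from trfscan.config import SimConfig
from trfscan import simulate


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """Moderate-depth configuration shared by unit tests."""
    return SimConfig(seed=123, read_depth=20_000)


@pytest.fixture(scope="session")
def toy(sim_config):
    """Toy genome plus tRNA loci."""
    return simulate.generate_toy_genome(sim_config)


@pytest.fixture(scope="session")
def readsets(sim_config, toy):
    genome, loci = toy
    return simulate.simulate_small_rna_reads(genome, loci, sim_config)
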