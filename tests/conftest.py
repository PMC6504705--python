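import pytest

from evopattern.io_core import SampleSeries
from evopattern.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def series():
    """The study layout: six cold then four hot samples."""
    return SampleSeries.default()


@pytest.fixture(scope="session")
def small_simulation():
    """A small seeded genome + annotation shared across tests."""
    cfg = SimulationConfig(seed=11, contig_length=50_000, n_genes=20,
                           gene_length=800)
    genome, genes, islands, go_map = simulate_genome(cfg)
    return cfg, genome, genes, islands, go_map
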