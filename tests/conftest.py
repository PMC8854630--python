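import pytest
from hypothesis import HealthCheck, settings

import graftrace as gt

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> gt.SimulationConfig:
    """Reduced design for fast unit tests: 12 genes, shallow sequencing."""
    return gt.SimulationConfig(
        seed=11,
        n_genes=12,
        gene_length_range=(400, 700),
        read_length=100,
        rna_depth=3000,
        dna_depth=15.0,
        n_conserved_genes=2,
        n_mobile_genes=2,
        n_de_genes=2,
    )


@pytest.fixture(scope="session")
def small_genomes(small_config):
    return gt.simulate_genomes(small_config)


@pytest.fixture(scope="session")
def small_transcripts(small_config, small_genomes):
    return gt.simulate_transcriptome(small_genomes, small_config)


@pytest.fixture(scope="session")
def small_reconstruction(small_config, small_genomes):
    dna = gt.simulate_dna_reads(small_genomes, small_config)
    return gt.reconstruct(dna, small_genomes.published_ref)
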