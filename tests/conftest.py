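import pytest

from oncohist.genomic_io import GeneModel, GenomeAnnotation, Interval
from oncohist.synthetic import SimConfig, generate_genome, plant_truth


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genes=300,
        n_chromosomes=2,
        chromosome_length=2_000_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_annotation):
    return plant_truth(small_annotation, small_config)


@pytest.fixture()
def toy_annotation() -> GenomeAnnotation:
    """Two genes on one 10 kb chromosome, one per strand."""
    return GenomeAnnotation(
        chrom_sizes={"chr1": 10_000},
        genes=[
            GeneModel(Interval("chr1", 2000, 4000), "+", "gplus"),
            GeneModel(Interval("chr1", 6000, 8000), "-", "gminus"),
        ],
    )
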