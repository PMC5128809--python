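import pytest

from bathypan import orthology, simulate
from bathypan.simulate import GenomePairSpec


@pytest.fixture(scope="session")
def desk_pair():
    """Desk-scale sister-genome pair (4 x 50 kb, 120 genes, 78% identity)."""
    spec = GenomePairSpec(seed=7)
    genome_a, genome_b, truth = simulate.simulate_genome_pair(spec)
    return spec, genome_a, genome_b, truth


@pytest.fixture(scope="session")
def desk_orthologs(desk_pair):
    _, genome_a, genome_b, _ = desk_pair
    return orthology.find_orthologs(genome_a, genome_b)


@pytest.fixture(scope="session")
def tiny_pair():
    """Single 5 kb chromosome per genome; cheap enough for brute-force checks."""
    spec = GenomePairSpec(
        n_chromosomes=1,
        chromosome_length=5_000,
        genes_per_chromosome=4,
        gene_length=600,
        outlier_chromosome_index=0,
        conserved_gene_count=0,
        seed=11,
    )
    genome_a, genome_b, truth = simulate.simulate_genome_pair(spec)
    return spec, genome_a, genome_b, truth
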