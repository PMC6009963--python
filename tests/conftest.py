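import pytest

from isokit.synthetic import generate_gene_models, generate_genome


@pytest.fixture(scope="session")
def toy_genome_genes():
    """A small annotated genome shared by read/isoform-level tests."""
    genome = generate_genome(3, 300_000, gc=0.45, seed=7)
    genes = generate_gene_models(
        genome, 12, exons_per_gene=(4, 6), exon_len=(150, 300), seed=1
    )
    return genome, genes


@pytest.fixture(scope="session")
def fusion_genome_genes():
    """Widely spaced genes so that every locus falls in its own 10 kb bin
    and same-contig loci are >= 100 kbp apart."""
    genome = generate_genome(4, 1_500_000, gc=0.45, seed=11)
    genes = generate_gene_models(
        genome, 24, exons_per_gene=(4, 6), exon_len=(200, 350),
        min_gap=110_000, seed=2,
    )
    return genome, genes
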