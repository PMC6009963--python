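"""Synthetic-data generator: determinism, structural invariants, planted
truth consistency, and error-rate realism."""

import numpy as np
import pytest

from isokit.models import ReadRecord, revcomp
from isokit.splicing import infer_as_events
from isokit.synthetic import (
    PRIMER_3P,
    PRIMER_5P,
    GenerationError,
    choose_fusion_pairs,
    generate_gene_models,
    generate_genome,
    plant_as_isoforms,
    simulate_long_reads,
    simulate_locus_links,
    simulate_short_read_support,
    spliced_slice_exons,
)


class TestGenome:
    def test_size_contract(self):
        g = generate_genome(1, 10_000, 0.5, seed=7)
        assert list(g.contigs) == ["contig1"]
        assert len(g["contig1"]) == 10_000

    def test_deterministic_per_seed(self):
        a = generate_genome(2, 5_000, 0.4, seed=7)
        b = generate_genome(2, 5_000, 0.4, seed=7)
        c = generate_genome(2, 5_000, 0.4, seed=8)
        assert a.contigs == b.contigs
        assert a.contigs != c.contigs

    def test_gc_content(self):
        g = generate_genome(3, 5_000, 0.30, seed=1)
        seq = "".join(g.contigs.values())
        gc = sum(ch in "GC" for ch in seq) / len(seq)
        assert abs(gc - 0.30) < 0.03

    @pytest.mark.parametrize("args", [(0, 5000, 0.5), (1, 500, 0.5), (1, 5000, 0.0)])
    def test_input_errors(self, args):
        with pytest.raises(ValueError):
            generate_genome(*args, seed=0)


class TestGeneModels:
    def test_counts_and_canonical_splice_sites(self):
        genome = generate_genome(2, 100_000, 0.45, seed=3)
        genes = generate_gene_models(genome, 10, exons_per_gene=(3, 5), seed=4)
        assert len(genes) == 10
        assert all(3 <= g.n_exons <= 5 for g in genes)
        for g in genes:
            seq = genome[g.contig]
            for s, e in g.introns:
                donor = seq[s : s + 2] if g.strand == "+" else revcomp(seq[e - 2 : e])
                acceptor = seq[e - 2 : e] if g.strand == "+" else revcomp(seq[s : s + 2])
                assert donor == "GT" and acceptor == "AG"

    def test_single_exon_genes_have_no_introns(self):
        genome = generate_genome(1, 50_000, 0.5, seed=0)
        genes = generate_gene_models(genome, 3, exons_per_gene=(1, 1), seed=0)
        assert all(g.introns == () for g in genes)

    def test_genes_do_not_overlap(self, toy_genome_genes):
        _, genes = toy_genome_genes
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append(g.span)
        for spans in by_contig.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_overflow_raises(self):
        genome = generate_genome(1, 1_000, 0.5, seed=0)
        with pytest.raises(GenerationError):
            generate_gene_models(genome, 50, seed=0)


class TestPlantedIsoforms:
    def test_es_drops_internal_exon(self, toy_genome_genes):
        _, genes = toy_genome_genes
        gene = genes[0]
        isos, truth = plant_as_isoforms(gene, ["ES"])
        (iso,) = isos
        assert iso.n_exons == gene.n_exons - 1
        skipped = truth[0][3]
        assert skipped in gene.exons and skipped not in iso.exons

    def test_ir_on_two_exon_gene_gives_single_exon_isoform(self):
        genome = generate_genome(1, 50_000, 0.5, seed=2)
        (gene,) = generate_gene_models(genome, 1, exons_per_gene=(2, 2), seed=2)
        isos, truth = plant_as_isoforms(gene, ["IR"])
        assert isos[0].n_exons == 1
        assert isos[0].span == gene.span
        assert truth[0][3] == gene.introns[0]

    def test_event_impossible_raises_naming_event(self):
        genome = generate_genome(1, 50_000, 0.5, seed=2)
        (gene,) = generate_gene_models(genome, 1, exons_per_gene=(2, 2), seed=2)
        with pytest.raises(ValueError, match="ES"):
            plant_as_isoforms(gene, ["ES"])  # needs >= 3 exons

    @pytest.mark.parametrize("spec", [["IR", "ES", "A5SS"], ["A3SS", "IR"], ["OTHER", "ES"]])
    def test_round_trip_through_as_caller(self, toy_genome_genes, spec):
        _, genes = toy_genome_genes
        gene = genes[2]
        isos, truth = plant_as_isoforms(gene, spec)
        events = infer_as_events([gene] + isos)
        got = sorted((e.type, e.coords) for e in events)
        want = sorted((t, c) for _, t, _, c in truth)
        assert got == want


class TestLongReads:
    def test_zero_noise_reads_equal_decorated_isoforms(self, toy_genome_genes):
        genome, genes = toy_genome_genes
        reads, truth = simulate_long_reads(
            genes, genome, n_reads=30, p=0.0, fl_fraction=1.0, seed=5
        )
        by_id = {r.read_id: r for r in reads}
        for rid, rt in truth.reads.items():
            iso = truth.isoforms[rt.source_isoforms[0]]
            expected = PRIMER_5P + iso.sequence(genome[iso.contig]) + "A" * 30 + PRIMER_3P
            assert by_id[rid].sequence == expected
            assert rt.n_errors == 0

    def test_reproducible_per_seed(self, toy_genome_genes):
        genome, genes = toy_genome_genes
        r1, _ = simulate_long_reads(genes, genome, n_reads=20, p=0.05, seed=9)
        r2, _ = simulate_long_reads(genes, genome, n_reads=20, p=0.05, seed=9)
        assert [(r.read_id, r.sequence) for r in r1] == [(r.read_id, r.sequence) for r in r2]

    def test_error_count_matches_binomial(self, toy_genome_genes):
        genome, genes = toy_genome_genes
        p = 0.05
        reads, truth = simulate_long_reads(
            genes, genome, n_reads=300, p=p, fl_fraction=1.0, seed=13
        )
        lens = []
        errs = []
        for rt in truth.reads.values():
            iso = truth.isoforms[rt.source_isoforms[0]]
            clean = len(PRIMER_5P) + iso.spliced_length + 30 + len(PRIMER_3P)
            lens.append(clean)
            errs.append(rt.n_errors)
        mean_expected = p * np.mean(lens)
        sd_of_mean = np.sqrt(p * (1 - p) * np.mean(lens) / len(errs))
        assert abs(np.mean(errs) - mean_expected) < 3 * sd_of_mean

    def test_fusion_reads_join_two_loci(self, fusion_genome_genes):
        genome, genes = fusion_genome_genes
        pairs = choose_fusion_pairs(genes, 5, seed=1)
        reads, truth = simulate_long_reads(
            genes, genome, n_reads=10, p=0.0, fusion_spec=pairs, seed=1
        )
        assert len(truth.fusions) == 5
        for rid, (ida, idb) in truth.fusions:
            segs = truth.reads[rid].segments
            assert len(segs) == 2
            a, b = truth.isoforms[ida], truth.isoforms[idb]
            assert segs[0].contig == a.contig and segs[1].contig == b.contig

    def test_empty_isoform_set_is_error(self, toy_genome_genes):
        genome, _ = toy_genome_genes
        with pytest.raises(ValueError):
            simulate_long_reads([], genome, n_reads=5, seed=0)

    def test_spliced_slice_respects_strand(self, toy_genome_genes):
        genome, genes = toy_genome_genes
        for gene in genes[:4]:
            full = gene.sequence(genome[gene.contig])
            chain = spliced_slice_exons(gene, 10, len(full) - 7)
            from dataclasses import replace

            sub = replace(gene, exons=chain)
            assert sub.sequence(genome[gene.contig]) == full[10 : len(full) - 7]


class TestShortReadSupport:
    def test_zero_depth_gives_zero_counts(self, toy_genome_genes):
        _, genes = toy_genome_genes
        table = simulate_short_read_support(genes, depth=0, seed=0)
        assert (table["count"] == 0).all()

    def test_counts_sum_over_isoforms(self, toy_genome_genes):
        _, genes = toy_genome_genes
        gene = genes[0]
        isos, _ = plant_as_isoforms(gene, ["ES"])
        depth = {gene.id: 10, isos[0].id: 20}
        table = simulate_short_read_support([gene, isos[0]], depth=depth, seed=0)
        shared = set(gene.junctions()) & set(isos[0].junctions())
        lut = {
            (r.contig, r.start, r.end, r.strand): r.count
            for r in table.itertuples(index=False)
        }
        for j in shared:
            assert lut[j] == 30
        for j in set(gene.junctions()) - shared:
            assert lut[j] == 10

    def test_locus_link_table_shape(self):
        df = simulate_locus_links([("c1:3", "c2:9")], n_pairs=5)
        assert list(df.columns) == ["locus_a", "locus_b", "n_pairs"]
        assert df.iloc[0]["n_pairs"] == 5
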