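"""Downstream filters: expression thresholds, tissue summaries, ORF
scanning, the lncRNA cascade, and homology-hit filtering."""

import numpy as np
import pandas as pd
import pytest

from isokit.filters import (
    expression_filter,
    homology_threshold_filter,
    intron_chain_match,
    lnc_cascade,
    longest_orf,
    tissue_summary,
    transcript_context,
)
from isokit.models import ExpressionRecord, TranscriptModel


def T(id, exons, strand="+", contig="chr1", gene_id=None):
    return TranscriptModel(id=id, contig=contig, strand=strand, exons=tuple(exons), gene_id=gene_id)


def rec(tid, tissue, repl, fpkm, matched=True):
    return ExpressionRecord(transcript_id=tid, tissue=tissue, replicate=repl,
                            fpkm=fpkm, intron_chain_matched=matched)


class TestIntronChainMatch:
    def test_end_differences_allowed(self):
        a = T("a", [(100, 200), (300, 400)])
        b = T("b", [(50, 200), (300, 480)])
        assert intron_chain_match(a, b)

    def test_extra_intron_fails(self):
        a = T("a", [(100, 200), (300, 400)])
        b = T("b", [(100, 150), (180, 200), (300, 400)])
        assert not intron_chain_match(a, b)

    def test_matches_tuple_comparison_on_fuzzed_pairs(self):
        rng = np.random.default_rng(67)
        for _ in range(200):
            n = int(rng.integers(1, 5))
            exons = []
            pos = 0
            for _e in range(n):
                pos += int(rng.integers(10, 50))
                end = pos + int(rng.integers(20, 80))
                exons.append((pos, end))
                pos = end
            a = T("a", exons)
            if rng.random() < 0.5:
                b = T("b", exons)
            else:
                shifted = [(s + (5 if i == 0 else 0), e) for i, (s, e) in enumerate(exons)]
                b = T("b", shifted)
            assert intron_chain_match(a, b) == (a.introns == b.introns)


class TestExpressionFilter:
    def test_boundary_two_replicates_at_min_fpkm(self):
        records = [rec("t1", "root", "r1", 0.01), rec("t1", "root", "r2", 0.01)]
        assert expression_filter(records) == {"root": {"t1"}}

    def test_one_passing_replicate_insufficient(self):
        records = [rec("t1", "root", "r1", 0.009), rec("t1", "root", "r2", 5.0)]
        assert expression_filter(records)["root"] == set()

    def test_unmatched_intron_chain_excluded(self):
        records = [rec("t1", "root", "r1", 2.0, matched=False),
                   rec("t1", "root", "r2", 2.0, matched=False)]
        assert expression_filter(records)["root"] == set()

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(71)
        records = [
            rec(f"t{i}", tissue, f"r{j}", float(rng.uniform(0, 0.05)))
            for i in range(30) for tissue in ("root", "leaf") for j in range(3)
        ]
        base = expression_filter(records, min_fpkm=0.01, min_replicates=2)
        stricter_fpkm = expression_filter(records, min_fpkm=0.02, min_replicates=2)
        stricter_reps = expression_filter(records, min_fpkm=0.01, min_replicates=3)
        for t in base:
            assert stricter_fpkm[t] <= base[t]
            assert stricter_reps[t] <= base[t]


class TestTissueSummary:
    def test_shared_and_specific(self):
        expressed = {
            "root": {"a", "b", "c"},
            "leaf": {"a", "b"},
            "node": {"a", "d"},
        }
        s = tissue_summary(expressed)
        assert s.shared_by_all == {"a"}
        assert s.tissue_specific == {"root": {"c"}, "leaf": set(), "node": {"d"}}
        assert s.per_tissue_counts["root"] == 3
        # invariants: shared within every tissue set; specific sets disjoint
        for t, ids in expressed.items():
            assert s.shared_by_all <= ids
        all_specific = [s.tissue_specific[t] for t in expressed]
        assert sum(map(len, all_specific)) == len(set().union(*all_specific))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            tissue_summary({})


class TestLongestOrf:
    def test_minimal_orf(self):
        assert longest_orf("ATGTAA") == 6

    def test_no_start_codon(self):
        assert longest_orf("CCCCCCCCCCTAACCC") == 0
        assert longest_orf("") == 0

    def test_start_without_stop_does_not_count(self):
        assert longest_orf("ATGAAAAAAAAA") == 0

    def test_matches_bruteforce_scanner(self):
        def brute(seq):
            best = 0
            for i in range(len(seq) - 2):
                if seq[i : i + 3] != "ATG":
                    continue
                for j in range(i + 3, len(seq) - 2, 3):
                    if seq[j : j + 3] in ("TAA", "TAG", "TGA"):
                        best = max(best, j + 3 - i)
                        break
            return best

        rng = np.random.default_rng(73)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            assert longest_orf(seq) == brute(seq)


class TestLncCascade:
    def _seq_with_orf(self, orf_nt):
        # ORF of exactly orf_nt (multiple of 3): ATG + codons + stop
        return "CC" + "ATG" + "GGC" * (orf_nt // 3 - 2) + "TAA" + "CC"

    def test_orf_boundary_350(self):
        # 351 nt exceeds the cutoff (use 352/349-adjacent multiples of 3)
        seqs = {"ok": self._seq_with_orf(348), "big": self._seq_with_orf(354)}
        out = {c.transcript_id: c for c in lnc_cascade(seqs, set(), {"ok": -2.0, "big": -2.0})}
        assert out["ok"].call == "strong"
        assert out["big"].call == "none" and out["big"].longest_orf_len == 354

    def test_score_boundaries(self):
        seqs = {x: self._seq_with_orf(90) for x in ("s", "w", "n")}
        scores = {"s": -1.001, "w": -1.0, "n": 0.2}
        out = {c.transcript_id: c.call for c in lnc_cascade(seqs, set(), scores)}
        assert out == {"s": "strong", "w": "weak", "n": "none"}

    def test_coding_hit_removed(self):
        seqs = {"t": self._seq_with_orf(90)}
        (cand,) = lnc_cascade(seqs, {"t"}, {})
        assert cand.call == "none" and cand.coding_hit

    def test_missing_score_is_error(self):
        with pytest.raises(ValueError):
            lnc_cascade({"t": self._seq_with_orf(90)}, set(), {})

    def test_stage_order_irrelevant(self):
        rng = np.random.default_rng(79)
        seqs, hits, scores = {}, set(), {}
        for i in range(50):
            tid = f"t{i}"
            seqs[tid] = self._seq_with_orf(int(rng.integers(2, 150)) * 3)
            if rng.random() < 0.3:
                hits.add(tid)
            scores[tid] = float(rng.uniform(-2, 1))
        calls = {c.transcript_id: c.call for c in lnc_cascade(seqs, hits, scores)}
        # independent evaluation: conjunction of the three stages
        for tid in seqs:
            strong = longest_orf(seqs[tid]) <= 350 and tid not in hits and scores[tid] < -1
            assert (calls[tid] == "strong") == strong

    def test_context_assignment(self):
        ann = [T("g1", [(1000, 1200), (1500, 1700)], gene_id="g1")]
        cases = {
            "sense": T("q1", [(1050, 1150)]),
            "antisense": T("q2", [(1050, 1150)], strand="-"),
            "intronic": T("q3", [(1300, 1400)]),
            "intergenic": T("q4", [(9000, 9100)]),
        }
        for want, model in cases.items():
            assert transcript_context(model, ann) == want


class TestHomologyFilter:
    def _table(self):
        rows = [
            # reciprocal best pair q1<->s1
            ("q1", "s1", 1e-12, 200), ("s1", "q1", 1e-12, 198),
            # q2's best is s2 but s2's best is q9 (not mutual)
            ("q2", "s2", 1e-15, 300), ("s2", "q9", 1e-30, 500), ("s2", "q2", 1e-15, 290),
            # fails e-value
            ("q3", "s3", 1e-8, 400), ("s3", "q3", 1e-8, 400),
        ]
        return pd.DataFrame(rows, columns=["query", "subject", "evalue", "bitscore"])

    def test_toy_reciprocal_table(self):
        kept = homology_threshold_filter(self._table(), 1e-10, 0.90, bidirectional=True)
        assert set(zip(kept["query"], kept["subject"])) == {("q1", "s1"), ("s1", "q1")}

    def test_evalue_cut_is_strict(self):
        df = pd.DataFrame([("q", "s", 1e-10, 100)], columns=["query", "subject", "evalue", "bitscore"])
        assert len(homology_threshold_filter(df, 1e-10, 0.9)) == 0

    def test_bscore_fraction_relative_to_best(self):
        df = pd.DataFrame(
            [("q", "s1", 1e-20, 100), ("q", "s2", 1e-20, 94), ("q", "s3", 1e-20, 80)],
            columns=["query", "subject", "evalue", "bitscore"],
        )
        kept = homology_threshold_filter(df, 1e-10, 0.93)
        assert list(kept["subject"]) == ["s1", "s2"]

    def test_malformed_row_reports_index(self):
        df = pd.DataFrame(
            [("q", "s", 1e-12, 100), ("q2", "s2", "oops", 90)],
            columns=["query", "subject", "evalue", "bitscore"],
        )
        with pytest.raises(ValueError, match="row 1"):
            homology_threshold_filter(df, 1e-10, 0.9)
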