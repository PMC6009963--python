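"""Downstream filter cascades: expression assignment, tissue summaries,
lncRNA candidacy, and homology-threshold filtering.

All boundary semantics follow the upstream conventions: FPKM >= 0.01 in at
least two replicates counts as expressed; a coding-potential score of
exactly -1 is a *weak* (not strong) non-coding call; an ORF of exactly
350 nt still qualifies a lncRNA candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .models import ExpressionRecord, LncCandidate, TranscriptModel

__all__ = [
    "intron_chain_match",
    "expression_filter",
    "TissueSummary",
    "tissue_summary",
    "longest_orf",
    "lnc_cascade",
    "transcript_context",
    "homology_threshold_filter",
]


def intron_chain_match(assembled: TranscriptModel, reference: TranscriptModel) -> bool:
    """Identical ordered intron chains on the same contig and strand;
    terminal-end differences are allowed."""
    return (
        assembled.contig == reference.contig
        and assembled.strand == reference.strand
        and assembled.introns == reference.introns
    )


def expression_filter(
    records: Iterable[ExpressionRecord],
    min_fpkm: float = 0.01,
    min_replicates: int = 2,
) -> Dict[str, Set[str]]:
    """Per-tissue expressed transcript sets.

    A transcript counts as expressed in a tissue when it is intron-chain
    matched and reaches ``min_fpkm`` (inclusive) in at least
    ``min_replicates`` replicates of that tissue.
    """
    hits: Dict[Tuple[str, str], int] = {}
    for r in records:
        if r.intron_chain_matched and r.fpkm >= min_fpkm:
            hits[(r.tissue, r.transcript_id)] = hits.get((r.tissue, r.transcript_id), 0) + 1
    out: Dict[str, Set[str]] = {}
    for (tissue, tid), n in hits.items():
        if n >= min_replicates:
            out.setdefault(tissue, set()).add(tid)
    # tissues observed but with nothing expressed still appear
    for r in records:
        out.setdefault(r.tissue, set())
    return out


@dataclass
class TissueSummary:
    per_tissue_counts: Dict[str, int]
    shared_by_all: Set[str]
    tissue_specific: Dict[str, Set[str]]

    @property
    def n_tissue_specific(self) -> int:
        return sum(len(s) for s in self.tissue_specific.values())


def tissue_summary(expressed: Mapping[str, Set[str]]) -> TissueSummary:
    """Per-tissue counts, the shared-by-all-tissues set, and the
    tissue-specific sets (expressed in exactly one tissue)."""
    if not expressed:
        raise ValueError("need at least one tissue")
    tissues = list(expressed)
    shared = set.intersection(*(set(expressed[t]) for t in tissues))
    seen_in: Dict[str, int] = {}
    for t in tissues:
        for tid in expressed[t]:
            seen_in[tid] = seen_in.get(tid, 0) + 1
    specific = {
        t: {tid for tid in expressed[t] if seen_in[tid] == 1} for t in tissues
    }
    return TissueSummary(
        per_tissue_counts={t: len(expressed[t]) for t in tissues},
        shared_by_all=shared,
        tissue_specific=specific,
    )


_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(sequence: str) -> int:
    """Longest ATG-to-stop open reading frame over the three forward
    frames of the given sense sequence, in nucleotides including the stop
    codon; 0 when no complete ORF exists."""
    seq = sequence.upper()
    best = 0
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def transcript_context(
    model: TranscriptModel, annotation: Sequence[TranscriptModel]
) -> str:
    """Genomic context of a transcript relative to protein-coding
    annotation: sense/antisense exonic overlap, intronic, or intergenic."""
    from .compare import _contains, _overlap  # shared interval helpers

    sense = antisense = intronic = False
    for t in annotation:
        if t.contig != model.contig:
            continue
        exonic = any(
            _overlap(qe, te) > 0 for qe in model.exons for te in t.exons
        )
        if exonic:
            if t.strand == model.strand:
                sense = True
            else:
                antisense = True
        elif any(_contains(it, model.span) for it in t.introns):
            intronic = True
    if sense:
        return "sense"
    if antisense:
        return "antisense"
    if intronic:
        return "intronic"
    return "intergenic"


def lnc_cascade(
    sequences: Mapping[str, str],
    coding_hits: Set[str],
    cp_scores: Mapping[str, float],
    max_orf: int = 350,
    strong_cut: float = -1.0,
    models: Optional[Mapping[str, TranscriptModel]] = None,
    annotation: Optional[Sequence[TranscriptModel]] = None,
) -> List[LncCandidate]:
    """The lncRNA candidacy cascade.

    A transcript is a candidate when its longest ORF is at most ``max_orf``
    nt (inclusive); candidates with a protein homology hit are removed;
    survivors are *strong* non-coding calls when the coding-potential score
    is strictly below ``strong_cut`` and *weak* when the score lies in
    [strong_cut, 0).  A surviving candidate without a score is an input
    error.  Genomic context is annotated when models + annotation are given.
    """
    out: List[LncCandidate] = []
    for tid, seq in sequences.items():
        orf = longest_orf(seq)
        hit = tid in coding_hits
        call = "none"
        score: Optional[float] = cp_scores.get(tid)
        if orf <= max_orf and not hit:
            if score is None:
                raise ValueError(f"no coding-potential score for candidate {tid}")
            if score < strong_cut:
                call = "strong"
            elif score < 0:
                call = "weak"
        context = "unknown"
        if models is not None and annotation is not None and tid in models:
            context = transcript_context(models[tid], annotation)
        out.append(
            LncCandidate(
                transcript_id=tid, longest_orf_len=orf, coding_hit=hit,
                cp_score=score, call=call, context=context,
            )
        )
    return out


def homology_threshold_filter(
    hits: pd.DataFrame,
    max_evalue: float,
    min_bscore_fraction: float,
    bidirectional: bool = False,
) -> pd.DataFrame:
    """Generic homology-hit filter.

    Keeps rows with e-value strictly below ``max_evalue`` and bit-score at
    least ``min_bscore_fraction`` of the query's best-hit bit-score; with
    ``bidirectional`` the (query, subject) pair must additionally be mutual
    best hits.  Typical settings: (1e-20, 0.93) for a conserved-protein
    screen, (1e-10, 0.90) for function transfer.
    """
    required = {"query", "subject", "evalue", "bitscore"}
    if not required <= set(hits.columns):
        raise ValueError(f"hit table needs columns {sorted(required)}")
    for i, row in enumerate(hits.itertuples(index=False)):
        try:
            float(row.evalue), float(row.bitscore)
        except (TypeError, ValueError):
            raise ValueError(f"malformed hit-table row {i}: {row}") from None
    if not len(hits):
        return hits.copy()
    df = hits.copy()
    df["evalue"] = df["evalue"].astype(float)
    df["bitscore"] = df["bitscore"].astype(float)
    best = df.groupby("query")["bitscore"].transform("max")
    kept = df[(df["evalue"] < max_evalue) & (df["bitscore"] >= min_bscore_fraction * best)]
    if bidirectional:
        best_partner = (
            df.sort_values(["bitscore"], ascending=False)
            .groupby("query")["subject"]
            .first()
            .to_dict()
        )
        mutual = kept.apply(
            lambda r: best_partner.get(r["subject"]) == r["query"]
            and best_partner.get(r["query"]) == r["subject"],
            axis=1,
        )
        kept = kept[mutual]
    return kept.reset_index(drop=True)
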