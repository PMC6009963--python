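"""Transcript-vs-annotation comparison.

Classifies each aligned transcript against a reference annotation into
nine mutually exclusive structural groups, summarizes gene-level
differences between the two gene sets, and collapses redundant
transcripts into unique isoforms by intron-chain identity.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .models import Interval, TranscriptModel

__all__ = [
    "CLASS_CODES",
    "GENE_DIFF_CATEGORIES",
    "classify_transcript",
    "classify_gene_difference",
    "collapse_transcripts",
    "remove_short_transcripts",
]

# strongest structural evidence first
CLASS_CODES = (
    "STRUCT_MATCH",
    "NOVEL_ISOFORM",
    "CONTAINED_IN_CDS",
    "CONTAINS_GENE",
    "GENE_IN_INTRON",
    "INTRONIC",
    "SAME_STRAND_PARTIAL",
    "OPPOSITE_STRAND_OVERLAP",
    "NOVEL_LOCUS",
)
_RANK = {c: i for i, c in enumerate(CLASS_CODES)}

GENE_DIFF_CATEGORIES = (
    "SPAN_MULTIPLE_LOCI",
    "SPLIT",
    "GENE_STRUCTURE",
    "SEQUENCE_SPAN",
    "UTR_ONLY",
    "IDENTICAL",
)
_DIFF_RANK = {c: i for i, c in enumerate(GENE_DIFF_CATEGORIES)}


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _reciprocal(a: Interval, b: Interval, frac: float) -> bool:
    ov = _overlap(a, b)
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])


def _contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def _properly_contains(outer: Interval, inner: Interval) -> bool:
    return _contains(outer, inner) and outer != inner


def _in_coding_region(query: TranscriptModel, t: TranscriptModel) -> bool:
    """Query properly contained in the coding (CDS-clipped exonic) region
    of ``t``: every query exon lies within a coding exon."""
    if t.cds is None or not _properly_contains(t.cds, query.span):
        return False
    cs, ce = t.cds
    coding = [(max(s, cs), min(e, ce)) for s, e in t.exons if min(e, ce) > max(s, cs)]
    return all(any(_contains(c, qe) for c in coding) for qe in query.exons)


def _group_genes(annotation: Sequence[TranscriptModel]) -> Dict[str, List[TranscriptModel]]:
    genes: Dict[str, List[TranscriptModel]] = {}
    for t in annotation:
        genes.setdefault(t.gene_id, []).append(t)
    return genes


def _gene_span(ts: Sequence[TranscriptModel]) -> Interval:
    return (min(t.start for t in ts), max(t.end for t in ts))


def classify_transcript(
    query: TranscriptModel,
    annotation: Sequence[TranscriptModel],
    single_exon_overlap: float = 0.5,
    known_contigs: Optional[Set[str]] = None,
) -> Tuple[str, Optional[str]]:
    """Assign exactly one of the nine class codes to ``query``.

    When several codes apply (possibly against different genes), the
    strongest structural evidence wins, in :data:`CLASS_CODES` order.
    Returns ``(code, matched_gene_id_or_None)``.
    """
    if known_contigs is not None and query.contig not in known_contigs:
        raise ValueError(f"query {query.id} is on unknown contig {query.contig}")
    best: Tuple[int, Optional[str]] = (_RANK["NOVEL_LOCUS"], None)

    def consider(code: str, gene_id: str) -> None:
        nonlocal best
        if _RANK[code] < best[0]:
            best = (_RANK[code], gene_id)

    for gene_id, ts in _group_genes(annotation).items():
        if ts[0].contig != query.contig:
            continue
        gspan = _gene_span(ts)
        if _overlap(query.span, gspan) <= 0 and not any(
            _contains(it, gspan) for it in query.introns
        ):
            continue
        same_strand = ts[0].strand == query.strand
        struct = novel_iso = False
        if same_strand:
            for t in ts:
                if query.n_exons > 1 and t.n_exons > 1:
                    if query.introns == t.introns:
                        struct = True
                    elif set(query.introns) & set(t.introns):
                        novel_iso = True
                elif query.n_exons == 1 and t.n_exons == 1:
                    if _reciprocal(query.span, t.span, single_exon_overlap):
                        struct = True
        if struct:
            consider("STRUCT_MATCH", gene_id)
        if novel_iso and not struct:
            consider("NOVEL_ISOFORM", gene_id)
        if any(_in_coding_region(query, t) for t in ts):
            consider("CONTAINED_IN_CDS", gene_id)
        gene_in_intron = any(_contains(it, gspan) for it in query.introns)
        if _properly_contains(query.span, gspan) and not gene_in_intron:
            consider("CONTAINS_GENE", gene_id)
        if gene_in_intron:
            consider("GENE_IN_INTRON", gene_id)
        if any(_contains(it, query.span) for t in ts for it in t.introns):
            consider("INTRONIC", gene_id)
        if any(
            _overlap(qex, tex) > 0
            for t in ts
            for tex in t.exons
            for qex in query.exons
        ) or _overlap(query.span, gspan) > 0:
            consider("SAME_STRAND_PARTIAL" if same_strand else "OPPOSITE_STRAND_OVERLAP", gene_id)

    code = CLASS_CODES[best[0]]
    return code, (best[1] if code != "NOVEL_LOCUS" else None)


# ---------------------------------------------------------------------------
# gene-level differences
# ---------------------------------------------------------------------------

def _is_terminal_extension(short: Tuple[Interval, ...], long: Tuple[Interval, ...]) -> bool:
    """True when the shorter intron chain occurs as a contiguous slice of
    the longer one (extra introns only at the termini)."""
    n, m = len(short), len(long)
    if n == 0:
        return False
    return any(long[i : i + n] == short for i in range(m - n + 1))


def _pair_category(q: TranscriptModel, r: TranscriptModel) -> str:
    if q.introns == r.introns:
        if q.n_exons > 1 or q.span == r.span:
            if q.span == r.span:
                return "IDENTICAL"
            if q.cds and r.cds and q.cds != r.cds:
                return "SEQUENCE_SPAN"
            return "UTR_ONLY"
        # both single-exon, different spans
        return "UTR_ONLY"
    if q.n_exons == 1 or r.n_exons == 1:
        return "GENE_STRUCTURE"
    short, long = sorted((q.introns, r.introns), key=len)
    if len(short) < len(long) and _is_terminal_extension(short, long):
        return "SEQUENCE_SPAN"
    return "GENE_STRUCTURE"


def classify_gene_difference(
    query_transcripts: Sequence[TranscriptModel],
    ref_gene: Sequence[TranscriptModel],
    annotation: Optional[Sequence[TranscriptModel]] = None,
) -> str:
    """Gene-level difference category between a matched query/reference
    gene pair, by the precedence SPAN_MULTIPLE_LOCI > SPLIT >
    GENE_STRUCTURE > SEQUENCE_SPAN > UTR_ONLY > IDENTICAL.

    ``annotation`` (the full reference transcript set) is needed to detect
    a query transcript spanning several reference genes.
    """
    if not query_transcripts or not ref_gene:
        raise ValueError("need transcripts on both sides")
    rspan = _gene_span(ref_gene)
    if not any(_overlap(q.span, rspan) > 0 for q in query_transcripts):
        raise ValueError("query gene does not overlap the reference gene")

    if annotation is not None:
        genes = _group_genes(annotation)
        for q in query_transcripts:
            n_hit = sum(
                1
                for ts in genes.values()
                if ts[0].contig == q.contig and _overlap(q.span, _gene_span(ts)) > 0
            )
            if n_hit >= 2:
                return "SPAN_MULTIPLE_LOCI"

    inside = [q for q in query_transcripts if _contains(rspan, q.span)]
    if len(inside) >= 2 and all(
        _overlap(a.span, b.span) == 0
        for i, a in enumerate(inside)
        for b in inside[i + 1 :]
    ):
        return "SPLIT"

    cats = []
    for q in query_transcripts:
        best_r = max(
            ref_gene,
            key=lambda r: (len(set(q.introns) & set(r.introns)), q.introns == r.introns),
        )
        cats.append(_pair_category(q, best_r))
    return min(cats, key=lambda c: _DIFF_RANK[c])


# ---------------------------------------------------------------------------
# transcript collapsing
# ---------------------------------------------------------------------------

def collapse_transcripts(
    transcripts: Sequence[TranscriptModel],
    single_exon_overlap: float = 0.5,
) -> List[TranscriptModel]:
    """Collapse redundant transcripts into unique isoforms.

    Spliced transcripts with identical intron chains merge into one isoform
    spanning the outermost observed ends; single-exon transcripts merge
    when reciprocally overlapping by at least ``single_exon_overlap``.
    A merged isoform is FL iff any member is.  Idempotent.
    """
    multi: Dict[Tuple, List[TranscriptModel]] = {}
    single: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for t in transcripts:
        if t.n_exons > 1:
            multi.setdefault((t.contig, t.strand, t.introns), []).append(t)
        else:
            single.setdefault((t.contig, t.strand), []).append(t)

    out: List[TranscriptModel] = []
    for (contig, strand, introns), members in multi.items():
        rep = min(members, key=lambda t: t.id)
        start = min(t.start for t in members)
        end = max(t.end for t in members)
        exons = list(rep.exons)
        exons[0] = (start, exons[0][1])
        exons[-1] = (exons[-1][0], end)
        out.append(
            replace(rep, exons=tuple(exons), is_fl=any(t.is_fl for t in members))
        )
    for (contig, strand), members in single.items():
        members = sorted(members, key=lambda t: (t.start, t.end, t.id))
        cluster: List[TranscriptModel] = []
        cspan: Optional[Interval] = None

        def flush() -> None:
            if not cluster:
                return
            rep = min(cluster, key=lambda t: t.id)
            out.append(
                replace(rep, exons=(cspan,), is_fl=any(t.is_fl for t in cluster))
            )

        for t in members:
            if cspan is not None and _reciprocal(cspan, t.span, single_exon_overlap):
                cluster.append(t)
                cspan = (min(cspan[0], t.start), max(cspan[1], t.end))
            else:
                flush()
                cluster = [t]
                cspan = t.span
        flush()
    return sorted(out, key=lambda t: (t.contig, t.start, t.id))


def remove_short_transcripts(
    isoforms: Iterable[TranscriptModel], min_len: int = 100
) -> List[TranscriptModel]:
    """Drop isoforms with spliced length below ``min_len`` (< 100 bp by
    default); length exactly ``min_len`` is kept."""
    return [t for t in isoforms if t.spliced_length >= min_len]
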