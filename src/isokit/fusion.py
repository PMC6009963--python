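"""Fusion-transcript calling from split alignments.

A transcript is called a fusion when its alignment splits across two or
more distinct loci such that (1) there are >= 2 loci, (2) every locus
covers at least 5% of the read, (3) the combined coverage over all loci is
at least 85% of the read, and (4) any two same-contig loci are at least
100 kbp apart (closer pairs are treated as one locus, not a fusion).
Redundant calls over the same breakpoints are grouped by their alignment
boundaries and represented by the longest transcript; paired short reads
linking the two loci validate a call.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .models import AlignmentSegment, FusionCall

__all__ = [
    "audit_fusion",
    "call_fusion",
    "group_by_boundaries",
    "classify_span",
    "locus_key",
    "validate_with_pairs",
    "unique_locus_pairs",
]

DEFAULT_BIN_WIDTH = 10_000


def audit_fusion(
    transcript_id: str,
    segments: Sequence[AlignmentSegment],
    read_length: int,
    min_frac: float = 0.05,
    min_combined: float = 0.85,
    min_distance: int = 100_000,
) -> Tuple[Optional[FusionCall], Optional[str]]:
    """Apply the four fusion criteria and report the first violated one.

    Returns ``(call, None)`` when all criteria hold and ``(None, reason)``
    otherwise, with reason in {'single_locus', 'min_frac', 'min_combined',
    'min_distance'}.  Overlapping read segments are an input error.
    """
    segs = sorted(segments, key=lambda s: s.read_start)
    for a, b in zip(segs, segs[1:]):
        if b.read_start < a.read_end:
            raise ValueError(
                f"read segments overlap on {transcript_id}: "
                f"{(a.read_start, a.read_end)} vs {(b.read_start, b.read_end)}"
            )
    if len(segs) < 2:
        return None, "single_locus"
    fracs = [s.read_span / read_length for s in segs]
    if any(f < min_frac for f in fracs):
        return None, "min_frac"
    if sum(fracs) < min_combined:
        return None, "min_combined"
    for i, a in enumerate(segs):
        for b in segs[i + 1 :]:
            if a.contig == b.contig:
                gap = max(b.start - a.end, a.start - b.end)
                if gap < min_distance:
                    return None, "min_distance"
    call = FusionCall(
        transcript_id=transcript_id,
        segments=tuple(segs),
        read_length=read_length,
        combined_coverage=sum(fracs),
    )
    return call, None


def call_fusion(
    transcript_id: str,
    segments: Sequence[AlignmentSegment],
    read_length: int,
    min_frac: float = 0.05,
    min_combined: float = 0.85,
    min_distance: int = 100_000,
) -> Optional[FusionCall]:
    """Apply the four fusion criteria to one read's split alignment;
    returns a :class:`FusionCall` iff all criteria hold, else ``None``."""
    call, _ = audit_fusion(
        transcript_id, segments, read_length,
        min_frac=min_frac, min_combined=min_combined, min_distance=min_distance,
    )
    return call


def classify_span(call: FusionCall) -> FusionCall:
    """Label a call inter- or intra-chromosomal; inter-contig calls also get
    a subtype (chromosome-chromosome / chromosome-scaffold / ...) based on
    contig naming."""
    contigs = {s.contig for s in call.segments}
    if len(contigs) > 1:
        call.span_class = "inter_chromosomal"
        kinds = sorted(
            "scaffold" if c.lower().startswith(("scaffold", "ctg", "contig")) else "chromosome"
            for c in contigs
        )
        call.span_subtype = "-".join(kinds[:2]) if len(contigs) == 2 else "multi"
    else:
        call.span_class = "intra_chromosomal"
        call.span_subtype = "same_contig"
    return call


def group_by_boundaries(calls: Sequence[FusionCall], tolerance: int = 50) -> List[FusionCall]:
    """Deduplicate calls whose corresponding segment boundaries all agree
    within ``tolerance`` bp; the longest transcript represents each group
    (ties broken by lexicographically smallest transcript_id).

    Idempotent and invariant to input order.
    """

    def close(a: FusionCall, b: FusionCall) -> bool:
        if len(a.segments) != len(b.segments):
            return False
        sa = sorted(a.segments, key=lambda s: (s.contig, s.start))
        sb = sorted(b.segments, key=lambda s: (s.contig, s.start))
        return all(
            x.contig == y.contig
            and abs(x.start - y.start) <= tolerance
            and abs(x.end - y.end) <= tolerance
            for x, y in zip(sa, sb)
        )

    ordered = sorted(calls, key=lambda c: (-c.read_length, c.transcript_id))
    reps: List[FusionCall] = []
    for c in ordered:
        if not any(close(c, r) for r in reps):
            reps.append(c)
    return sorted(reps, key=lambda c: c.transcript_id)


def locus_key(contig: str, start: int, end: int, bin_width: int = DEFAULT_BIN_WIDTH) -> str:
    """Binned locus identifier used to match long-read segments against
    short-read locus links: contig plus the bin of the segment midpoint."""
    mid = (start + end) // 2
    return f"{contig}:{mid // bin_width}"


def _pair_key(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def call_locus_pairs(call: FusionCall, bin_width: int = DEFAULT_BIN_WIDTH) -> Set[Tuple[str, str]]:
    keys = [locus_key(s.contig, s.start, s.end, bin_width) for s in call.segments]
    return {
        _pair_key(keys[i], keys[j])
        for i in range(len(keys))
        for j in range(i + 1, len(keys))
    }


def validate_with_pairs(
    call: FusionCall,
    pair_table: pd.DataFrame,
    min_pairs: int = 5,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> FusionCall:
    """Validate a call against a paired-read locus-link table (columns
    locus_a, locus_b, n_pairs); validated iff every segment pair is linked
    by at least ``min_pairs`` read pairs (inclusive)."""
    support: Dict[Tuple[str, str], int] = {}
    for row in pair_table.itertuples(index=False):
        key = _pair_key(str(row.locus_a), str(row.locus_b))
        support[key] = support.get(key, 0) + int(row.n_pairs)
    counts = [support.get(k, 0) for k in call_locus_pairs(call, bin_width)]
    call.n_supporting_pairs = min(counts) if counts else 0
    call.validated = bool(counts) and all(c >= min_pairs for c in counts)
    return call


def unique_locus_pairs(
    calls: Iterable[FusionCall], bin_width: int = DEFAULT_BIN_WIDTH
) -> Dict[Tuple[str, str], Dict[str, int]]:
    """Distinct unordered locus pairs covered by a (deduplicated) call set,
    with per-pair tallies of supporting calls and validated calls."""
    out: Dict[Tuple[str, str], Dict[str, int]] = {}
    for call in calls:
        for key in call_locus_pairs(call, bin_width):
            rec = out.setdefault(key, {"n_calls": 0, "n_validated": 0})
            rec["n_calls"] += 1
            rec["n_validated"] += int(call.validated)
    return out
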