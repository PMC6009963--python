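"""Alternative-splicing event calling and validation.

Events are found by pairwise structural comparison of the intron chains of
a locus's isoforms:

* IR   - one isoform's exon fully spans another's intron;
* ES   - an internal exon of one isoform lies entirely within an intron of
         another;
* A5SS - two introns share their acceptor but differ at the donor
         (5' side, relative to transcription direction);
* A3SS - two introns share their donor but differ at the acceptor;
* OTHER - a transcript starts or ends inside another's intron, or the
         isoforms differ without matching any pattern above (alternative
         terminal exons).

A shared-boundary intron pair whose differing stretch swallows a complete
exon of the shorter-intron isoform is the junction signature of exon
skipping and is not double-reported as A5SS/A3SS.  Duplicate events (same
type and variable-region coordinates) across isoform pairs are reported
once, with all participating isoforms attached.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .models import ASEvent, Interval, JunctionSupport, TranscriptModel, junction_key

__all__ = [
    "infer_as_events",
    "label_as_transcripts",
    "junction_support",
    "validate_as_event",
    "validate_with_reference_transcripts",
    "junction_motifs",
]

EVENT_TYPES = ("IR", "A3SS", "A5SS", "ES", "OTHER")


def _exon_in(region: Interval, exons: Sequence[Interval]) -> bool:
    return any(region[0] <= s and e <= region[1] for s, e in exons)


def _pair_events(
    a: TranscriptModel, b: TranscriptModel
) -> List[Tuple[str, Interval, frozenset, frozenset]]:
    """Typed events between two isoforms: (type, coords, incl_j, excl_j)."""
    out: List[Tuple[str, Interval, frozenset, frozenset]] = []
    strand = a.strand
    jk = lambda iv, m: junction_key(m.contig, iv[0], iv[1], m.strand)

    for x, y in ((a, b), (b, a)):
        # IR: exon of x retains an intron of y
        for ex in x.exons:
            for it in y.introns:
                if ex[0] <= it[0] and it[1] <= ex[1]:
                    out.append(("IR", it, frozenset(), frozenset({jk(it, y)})))
        # ES: internal exon of x skipped by an intron of y
        for ex in x.exons[1:-1]:
            for it in y.introns:
                if it[0] <= ex[0] and ex[1] <= it[1]:
                    flanks = [i for i in x.introns if i[1] == ex[0] or i[0] == ex[1]]
                    out.append(
                        ("ES", ex,
                         frozenset(jk(i, x) for i in flanks),
                         frozenset({jk(it, y)}))
                    )
        # OTHER: x starts or ends strictly inside an intron of y
        for it in y.introns:
            for pos in (x.start, x.end):
                if it[0] < pos < it[1] and not any(
                    ex[0] <= it[0] and it[1] <= ex[1] for ex in x.exons
                ):
                    out.append(("OTHER", it, frozenset(), frozenset({jk(it, y)})))

    # A5SS / A3SS: shared-boundary intron pairs
    for ia in a.introns:
        for ib in b.introns:
            if ia == ib:
                continue
            if ia[0] == ib[0] and ia[1] != ib[1]:
                lo, hi = sorted((ia[1], ib[1]))
                shorter, longer = (a, b) if ia[1] < ib[1] else (b, a)
                if _exon_in((lo, hi), shorter.exons):
                    continue  # exon-skipping signature, reported as ES
                etype = "A3SS" if strand == "+" else "A5SS"
                short_iv, long_iv = (ia, ib) if ia[1] < ib[1] else (ib, ia)
                out.append(
                    (etype, (lo, hi),
                     frozenset({jk(short_iv, shorter)}),
                     frozenset({jk(long_iv, longer)}))
                )
            elif ia[1] == ib[1] and ia[0] != ib[0]:
                lo, hi = sorted((ia[0], ib[0]))
                shorter, longer = (a, b) if ia[0] > ib[0] else (b, a)
                if _exon_in((lo, hi), shorter.exons):
                    continue
                etype = "A5SS" if strand == "+" else "A3SS"
                short_iv, long_iv = (ia, ib) if ia[0] > ib[0] else (ib, ia)
                out.append(
                    (etype, (lo, hi),
                     frozenset({jk(short_iv, shorter)}),
                     frozenset({jk(long_iv, longer)}))
                )

    if not out and set(a.introns) != set(b.introns):
        # structural difference with no typed pattern: alternative
        # terminal exons and the like
        diff = sorted(set(a.introns) ^ set(b.introns))
        coords = (min(s for s, _ in diff), max(e for _, e in diff))
        out.append(("OTHER", coords, frozenset(), frozenset()))
    return out


def infer_as_events(
    isoforms: Sequence[TranscriptModel], gene_id: Optional[str] = None
) -> List[ASEvent]:
    """Enumerate deduplicated AS events among one locus's isoforms.

    Isoforms must share a contig and strand (mixed strands are an input
    error).  Events identical in (type, coordinates) across pairs are
    reported once with the union of participating isoforms.
    """
    if len(isoforms) < 2:
        return []
    contigs = {m.contig for m in isoforms}
    strands = {m.strand for m in isoforms}
    if len(contigs) > 1 or len(strands) > 1:
        raise ValueError("isoforms of one locus must share contig and strand")
    gid = gene_id or isoforms[0].gene_id
    acc: Dict[Tuple[str, Interval], ASEvent] = {}
    for i, a in enumerate(isoforms):
        for b in isoforms[i + 1 :]:
            for etype, coords, incl, excl in _pair_events(a, b):
                key = (etype, coords)
                prev = acc.get(key)
                if prev is None:
                    acc[key] = ASEvent(
                        gene_id=gid, type=etype, contig=a.contig, coords=coords,
                        strand=a.strand, inclusion_junctions=incl,
                        exclusion_junctions=excl,
                        isoform_ids=frozenset({a.id, b.id}),
                    )
                else:
                    acc[key] = ASEvent(
                        gene_id=gid, type=etype, contig=a.contig, coords=coords,
                        strand=a.strand,
                        inclusion_junctions=prev.inclusion_junctions | incl,
                        exclusion_junctions=prev.exclusion_junctions | excl,
                        isoform_ids=prev.isoform_ids | {a.id, b.id},
                    )
    return sorted(acc.values(), key=lambda e: (e.coords, e.type))


def label_as_transcripts(
    isoforms: Sequence[TranscriptModel], events: Sequence[ASEvent]
) -> Dict[str, bool]:
    """Flag each isoform as an AS transcript iff it participates in at
    least one event."""
    involved: Set[str] = set()
    for e in events:
        involved |= e.isoform_ids
    return {m.id: m.id in involved for m in isoforms}


def junction_support(
    junctions: Sequence[Tuple[str, int, int, str]],
    table: pd.DataFrame,
    min_reads: int = 5,
    mode: str = "any_sample",
) -> Tuple[List[JunctionSupport], float]:
    """Short-read support per junction.

    ``table`` has columns (sample, contig, start, end, strand, count); a
    junction is supported when its count reaches ``min_reads`` in at least
    one sample (``mode='any_sample'``) or on average over samples
    (``mode='mean'``).  Returns the per-junction report and the supported
    fraction.
    """
    if mode not in ("any_sample", "mean"):
        raise ValueError("mode must be 'any_sample' or 'mean'")
    if len(table):
        grouped = table.groupby(["contig", "start", "end", "strand"])["count"]
        stat = grouped.max() if mode == "any_sample" else grouped.mean()
        lookup = stat.to_dict()
    else:
        lookup = {}
    out = []
    for j in junctions:
        n = lookup.get(tuple(j), 0)
        out.append(JunctionSupport(junction=tuple(j), n_reads=int(n), supported=n >= min_reads))
    frac = sum(s.supported for s in out) / len(out) if out else 0.0
    return out, frac


def validate_as_event(
    event: ASEvent, inclusion_reads: int, exclusion_reads: int,
    min_each: int = 1, min_total: int = 10,
) -> bool:
    """Short-read validation rule: at least one inclusion read, at least
    one exclusion read, and at least ten reads in total (all inclusive)."""
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise ValueError("read counts must be non-negative")
    return (
        inclusion_reads >= min_each
        and exclusion_reads >= min_each
        and inclusion_reads + exclusion_reads >= min_total
    )


def validate_with_reference_transcripts(
    event: ASEvent, references: Sequence[TranscriptModel]
) -> Optional[bool]:
    """Validate IR/ES events against independent reference transcripts
    (e.g. Sanger-sequenced cDNAs aligned to the same genome).

    An IR event is validated when some reference exon fully covers the
    retained intron; an ES event when some reference intron fully covers
    the skipped exon.  Other event types are not applicable (``None``).
    """
    lo, hi = event.coords
    refs = [r for r in references if r.contig == event.contig]
    if event.type == "IR":
        return any(s <= lo and hi <= e for r in refs for s, e in r.exons)
    if event.type == "ES":
        return any(s <= lo and hi <= e for r in refs for s, e in r.introns)
    return None


def junction_motifs(
    model: TranscriptModel, contig_seq: str
) -> List[Tuple[Tuple[str, int, int, str], str, bool]]:
    """Donor..acceptor dinucleotides of each junction on the coding strand,
    with a canonical (GT-AG or GC-AG) flag."""
    from .models import revcomp

    out = []
    for s, e in model.introns:
        if model.strand == "+":
            motif = contig_seq[s : s + 2] + contig_seq[e - 2 : e]
        else:
            motif = revcomp(contig_seq[e - 2 : e]) + revcomp(contig_seq[s : s + 2])
        out.append(
            (junction_key(model.contig, s, e, model.strand), motif,
             motif in ("GTAG", "GCAG"))
        )
    return out
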