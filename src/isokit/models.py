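"""Core data model shared by every isokit module.

The universal currency is :class:`TranscriptModel`: a strand-aware chain of
exons on one contig, used interchangeably for annotated genes, assembled
isoforms, and long reads as aligned to the genome.  All coordinates are
0-based, half-open; conversion to 1-based closed happens only at GTF
emission time (see :mod:`isokit.gtfio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

Interval = Tuple[int, int]

__all__ = [
    "Interval",
    "TranscriptModel",
    "ReadRecord",
    "TriageResult",
    "AlignmentSegment",
    "TranscriptAlignment",
    "MismapVerdict",
    "FusionCall",
    "ASEvent",
    "JunctionSupport",
    "ExpressionRecord",
    "LncCandidate",
    "junction_key",
]


def _check_intervals(ivs: Sequence[Interval]) -> None:
    for s, e in ivs:
        if not (0 <= s < e):
            raise ValueError(f"bad interval {(s, e)}")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"intervals overlap or are unsorted: {(s1, e1)} vs {(s2, e2)}")


@dataclass
class TranscriptModel:
    """A strand-aware exon chain on a contig.

    Parameters
    ----------
    id : str
        Transcript identifier.
    contig, strand : str
        Genomic location; strand is ``'+'`` or ``'-'``.
    exons : sequence of (start, end)
        Sorted, disjoint, 0-based half-open exon intervals.
    gene_id : str, optional
        Owning locus (defaults to ``id``).
    cds : (start, end), optional
        Genomic span of the coding region, if known.
    is_fl : bool
        Whether the underlying evidence is a full-length read; survives
        transcript collapsing (a merged isoform is FL iff any member is).
    """

    id: str
    contig: str
    strand: str
    exons: Tuple[Interval, ...]
    gene_id: Optional[str] = None
    cds: Optional[Interval] = None
    is_fl: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValueError("a transcript needs at least one exon")
        _check_intervals(self.exons)
        if self.gene_id is None:
            self.gene_id = self.id

    # -- basic geometry ------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> Tuple[Interval, ...]:
        """Gaps between consecutive exons (empty for single-exon models)."""
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    @property
    def intron_chain(self) -> Tuple[Interval, ...]:
        return self.introns

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junctions(self) -> Tuple[Tuple[str, int, int, str], ...]:
        """Splice junctions as (contig, intron_start, intron_end, strand) keys."""
        return tuple(junction_key(self.contig, s, e, self.strand) for s, e in self.introns)

    def donor_acceptor(self, intron: Interval) -> Tuple[int, int]:
        """Genomic positions of the donor (5') and acceptor (3') site of an
        intron, respecting strand: on '+' the donor is the intron start."""
        s, e = intron
        return (s, e) if self.strand == "+" else (e, s)

    def sequence(self, contig_seq: str) -> str:
        """Spliced (sense-strand) sequence given the contig sequence."""
        seq = "".join(contig_seq[s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def with_id(self, new_id: str) -> "TranscriptModel":
        return replace(self, id=new_id)


def junction_key(contig: str, start: int, end: int, strand: str) -> Tuple[str, int, int, str]:
    return (contig, int(start), int(end), strand)


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# read triage
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """A raw long read plus the per-base error rate of its library."""

    read_id: str
    sequence: str
    library_id: str = "lib0"
    error_rate: float = 0.02

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("library error rate must be in [0, 1)")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TriageResult:
    """Outcome of signal classification for one read.

    ``signal_class`` is one of the eight combinations of (5' primer found,
    3' primer found, polyA found); ``'FL'`` iff all three are present.
    """

    read_id: str
    has_5p: bool
    has_3p: bool
    has_polya: bool
    length: int
    length_pass: bool = True
    concatemer: bool = False
    orientation: str = "+"

    @property
    def is_fl(self) -> bool:
        return self.has_5p and self.has_3p and self.has_polya

    @property
    def signal_class(self) -> str:
        if self.is_fl:
            return "FL"
        missing = []
        if not self.has_5p:
            missing.append("5p")
        if not self.has_3p:
            missing.append("3p")
        if not self.has_polya:
            missing.append("polyA")
        return "missing_" + "+".join(missing)


#: the eight mutually exclusive signal classes, FL first
SIGNAL_CLASSES = (
    "FL",
    "missing_5p",
    "missing_3p",
    "missing_polyA",
    "missing_5p+3p",
    "missing_5p+polyA",
    "missing_3p+polyA",
    "missing_5p+3p+polyA",
)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSegment:
    """One aligned piece of a read (a split alignment has several)."""

    contig: str
    start: int
    end: int
    strand: str
    read_start: int
    read_end: int

    @property
    def genomic_span(self) -> int:
        return self.end - self.start

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class TranscriptAlignment:
    """A read-to-genome alignment with its error accounting.

    ``L`` is the aligned length in bases and ``K`` the number of errors
    (mismatches plus indel bases) over those bases, so identity is
    ``(L - K) / L``.  ``coverage`` is the fraction of the read aligned.
    """

    read_id: str
    contig: str
    strand: str
    blocks: Tuple[Interval, ...]
    L: int
    K: int
    read_length: int
    segments: Tuple[AlignmentSegment, ...] = ()
    truth_correct_locus: Optional[bool] = None

    def __post_init__(self) -> None:
        self.blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        _check_intervals(self.blocks)
        if not (0 <= self.K <= self.L):
            raise ValueError(f"need 0 <= K <= L, got K={self.K}, L={self.L}")

    @property
    def identity(self) -> float:
        if self.L == 0:
            raise ValueError("empty alignment has no identity")
        return (self.L - self.K) / self.L

    @property
    def coverage(self) -> float:
        return min(1.0, self.L / self.read_length)

    @property
    def is_split(self) -> bool:
        return len(self.segments) > 1

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    def to_model(self, transcript_id: Optional[str] = None) -> TranscriptModel:
        return TranscriptModel(
            id=transcript_id or self.read_id,
            contig=self.contig,
            strand=self.strand,
            exons=self.blocks,
        )


@dataclass
class MismapVerdict:
    """Decision of the statistical mis-mapping test for one alignment."""

    read_id: str
    K: int
    L: int
    p: float
    pvalue: float
    threshold_K: float
    flagged: bool


# ---------------------------------------------------------------------------
# fusions
# ---------------------------------------------------------------------------

@dataclass
class FusionCall:
    """A transcript split-mapped to two or more distant loci."""

    transcript_id: str
    segments: Tuple[AlignmentSegment, ...]
    read_length: int
    combined_coverage: float
    span_class: str = ""          # inter_chromosomal / intra_chromosomal
    span_subtype: str = ""        # e.g. chromosome-scaffold
    validated: bool = False
    n_supporting_pairs: int = 0

    def segment_fractions(self) -> Tuple[float, ...]:
        return tuple(s.read_span / self.read_length for s in self.segments)


# ---------------------------------------------------------------------------
# alternative splicing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ASEvent:
    """A typed splicing difference between two isoforms of a locus.

    ``coords`` is the genomic interval of the variable region: the retained
    intron (IR), the skipped exon (ES), the stretch between the two
    alternative donor/acceptor sites (A5SS/A3SS), or the host intron of the
    deviant boundary (OTHER).
    """

    gene_id: str
    type: str                     # IR / A3SS / A5SS / ES / OTHER
    contig: str
    coords: Interval
    strand: str
    inclusion_junctions: frozenset = frozenset()
    exclusion_junctions: frozenset = frozenset()
    isoform_ids: frozenset = frozenset()

    @property
    def key(self) -> Tuple[str, str, Interval]:
        return (self.type, self.contig, self.coords)


@dataclass
class JunctionSupport:
    junction: Tuple[str, int, int, str]
    n_reads: int
    supported: bool


# ---------------------------------------------------------------------------
# expression / lncRNA
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRecord:
    transcript_id: str
    tissue: str
    replicate: str
    fpkm: float
    intron_chain_matched: bool = True

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError("FPKM must be non-negative")


@dataclass
class LncCandidate:
    transcript_id: str
    longest_orf_len: int
    coding_hit: bool
    cp_score: Optional[float]
    call: str                    # strong / weak / none
    context: str = "unknown"     # intergenic / intronic / antisense / sense
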