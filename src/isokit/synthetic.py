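"""Ground-truth transcriptome simulator.

Generates a toy multi-contig genome, strand-aware multi-exon gene models
with canonical GT..AG introns, isoforms carrying planted alternative
splicing events, error-bearing long reads (full-length, truncated non-FL,
chimeric fusion, concatemer), and short-read junction/locus-link support
tables.  Every simulated object is recorded in a :class:`PlantedTruth`
sidecar so downstream modules can be scored against exact truth.

Defaults mirror a PacBio-style Iso-Seq library over a compact plant
genome: per-base error rates within the observed 0.0072-0.055 library
range, indel-heavy errors (indel:substitution 2:1), a 5'/3' PCR-primer
pair plus a >= 20 nt polyA tail decorating full-length reads, and a
non-FL signal-class mix dominated by reads missing all signals (47%),
missing the 3' primer and polyA (21%), or missing the 5' primer (22%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .models import AlignmentSegment, Interval, TranscriptModel, revcomp

__all__ = [
    "GenerationError",
    "SyntheticGenome",
    "ReadTruth",
    "PlantedTruth",
    "PRIMER_5P",
    "PRIMER_3P",
    "DEFAULT_NONFL_CLASSES",
    "generate_genome",
    "generate_gene_models",
    "plant_as_isoforms",
    "simulate_long_reads",
    "simulate_short_read_support",
    "simulate_locus_links",
    "choose_fusion_pairs",
    "spliced_slice_exons",
]

# Template-switching 5' primer and the (reverse-complemented) PCR primer
# appearing downstream of the polyA tail in sense-strand reads.
PRIMER_5P = "TAGTCGAACTGAGATCTCCAGCAGTACGGG"
PRIMER_3P = revcomp("TAGTCGAACTGAGATCTCCAGCAG")

#: default non-FL signal-class mix as (has_5p, has_3p, has_polyA) -> weight.
#: Dominant classes: missing everything, missing 3'+polyA, missing 5';
#: the remaining 10% is spread uniformly over the other four combinations.
DEFAULT_NONFL_CLASSES: Dict[Tuple[bool, bool, bool], float] = {
    (False, False, False): 0.47,
    (True, False, False): 0.21,
    (False, True, True): 0.22,
    (True, True, False): 0.025,
    (True, False, True): 0.025,
    (False, True, False): 0.025,
    (False, False, True): 0.025,
}


class GenerationError(RuntimeError):
    """Raised when the requested synthetic layout cannot be produced."""


@dataclass
class SyntheticGenome:
    """An ordered set of contigs (id -> uppercase ACGT sequence)."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.contigs)) != len(self.contigs):
            raise ValueError("contig ids must be unique")
        for name, seq in self.contigs.items():
            if len(seq) < 1000:
                raise ValueError(f"contig {name} shorter than 1 kb")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} has non-ACGT characters")

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def items(self):
        return self.contigs.items()

    def to_fasta(self, path: str) -> None:
        from .gtfio import write_fasta

        write_fasta(self.contigs.items(), path)


@dataclass
class ReadTruth:
    """Ground truth for one simulated long read."""

    read_id: str
    source_isoforms: Tuple[str, ...]
    has_5p: bool
    has_3p: bool
    has_polya: bool
    error_rate: float
    n_errors: int
    read_length: int
    is_fusion: bool = False
    is_concatemer: bool = False
    segments: Tuple[AlignmentSegment, ...] = ()
    aligned_model: Optional[TranscriptModel] = None

    @property
    def is_fl(self) -> bool:
        return self.has_5p and self.has_3p and self.has_polya


@dataclass
class PlantedTruth:
    """The simulator's complete record of what it planted."""

    isoforms: Dict[str, TranscriptModel] = field(default_factory=dict)
    events: List[Tuple[str, str, str, Interval]] = field(default_factory=list)
    fusions: List[Tuple[str, Tuple[str, str]]] = field(default_factory=list)
    reads: Dict[str, ReadTruth] = field(default_factory=dict)

    def event_multiset(self) -> Dict[Tuple[str, str, Interval], int]:
        out: Dict[Tuple[str, str, Interval], int] = {}
        for _iso, etype, contig, coords in self.events:
            key = (etype, contig, coords)
            out[key] = out.get(key, 0) + 1
        return out


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def generate_genome(
    n_contigs: int, contig_length: int, gc: float = 0.45, seed: int = 0
) -> SyntheticGenome:
    """Random genome with the requested GC content; deterministic per seed."""
    if n_contigs < 1 or contig_length < 1000:
        raise ValueError("need n_contigs >= 1 and contig_length >= 1000")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contigs = {}
    for i in range(n_contigs):
        seq = "".join(rng.choice(_BASES, size=contig_length, p=probs))
        contigs[f"contig{i + 1}"] = seq
    return SyntheticGenome(contigs)


def generate_gene_models(
    genome: SyntheticGenome,
    n_genes: int,
    exons_per_gene: Tuple[int, int] = (3, 5),
    exon_len: Tuple[int, int] = (80, 300),
    intron_len: Tuple[int, int] = (60, 400),
    min_gap: int = 500,
    seed: int = 0,
    with_cds: bool = True,
) -> List[TranscriptModel]:
    """Place non-overlapping genes on both strands and write canonical
    splice dinucleotides (GT..AG on the coding strand) into the genome.

    The genome's contig sequences are modified in place at the emitted
    intron boundaries.  Raises :class:`GenerationError` when the genes do
    not fit without overlap.
    """
    rng = np.random.default_rng(seed)
    cursors = {name: min_gap for name in genome.contigs}
    genes: List[TranscriptModel] = []
    contig_names = list(genome.contigs)
    mutable = {name: list(seq) for name, seq in genome.contigs.items()}

    for gi in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        ex_lens = rng.integers(exon_len[0], exon_len[1] + 1, size=n_ex)
        in_lens = rng.integers(intron_len[0], intron_len[1] + 1, size=max(0, n_ex - 1))
        glen = int(ex_lens.sum() + in_lens.sum())
        placed = False
        for name in sorted(contig_names, key=lambda c: cursors[c]):
            start = cursors[name] + int(rng.integers(0, min_gap))
            if start + glen + min_gap <= len(genome.contigs[name]):
                cursors[name] = start + glen + min_gap
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"cannot place gene {gi + 1}/{n_genes} without overlap; "
                "enlarge the genome or reduce gene sizes"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for j, el in enumerate(ex_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_ex - 1:
                pos += int(in_lens[j])
        gene_id = f"g{gi + 1:04d}"
        cds = None
        if with_cds and exons[-1][1] - exons[0][0] > 120:
            cds = (exons[0][0] + 30, exons[-1][1] - 30)
        gene = TranscriptModel(
            id=gene_id, contig=name, strand=strand, exons=tuple(exons),
            gene_id=gene_id, cds=cds,
        )
        # canonical splice dinucleotides on the coding strand
        for s, e in gene.introns:
            if strand == "+":
                mutable[name][s : s + 2] = ["G", "T"]
                mutable[name][e - 2 : e] = ["A", "G"]
            else:
                mutable[name][s : s + 2] = ["C", "T"]
                mutable[name][e - 2 : e] = ["A", "C"]
        genes.append(gene)

    for name in genome.contigs:
        genome.contigs[name] = "".join(mutable[name])
    return genes


# ---------------------------------------------------------------------------
# planting AS isoforms
# ---------------------------------------------------------------------------

_EVENT_ORDER = {"OTHER": 0, "ES": 1, "IR": 2, "A5SS": 3, "A3SS": 3}


def plant_as_isoforms(
    gene: TranscriptModel,
    event_spec: Sequence[str],
    shift: int = 12,
) -> Tuple[List[TranscriptModel], List[Tuple[str, str, str, Interval]]]:
    """Derive one isoform per requested event from a reference gene model.

    Each emitted isoform differs from the reference by exactly the planted
    event.  Events are assigned to distinct introns/exons (an OTHER event
    claims a terminal intron, an ES event shields its flanking introns from
    IR) so that pairwise comparison of the full isoform set recovers
    exactly the planted event multiset.  Raises ``ValueError`` naming the
    event when the gene shape cannot host it.
    """
    introns = gene.introns
    exons = gene.exons
    n_in, n_ex = len(introns), len(exons)
    used_introns: set = set()
    ir_blocked: set = set()
    used_exons: set = set()
    other_slots = ["start", "end"]

    # assignment pass (OTHER, then ES, then IR, then A5SS/A3SS)
    order = sorted(range(len(event_spec)), key=lambda i: _EVENT_ORDER.get(event_spec[i], 9))
    targets: Dict[int, Tuple[str, int]] = {}
    for i in order:
        etype = event_spec[i]
        if etype == "OTHER":
            if n_in < 1 or n_ex < 2 or not other_slots:
                raise ValueError(f"cannot plant OTHER in gene {gene.id}: no free terminal intron")
            slot = other_slots.pop(0)
            idx = 0 if slot == "start" else n_in - 1
            if idx in used_introns:
                raise ValueError(f"cannot plant OTHER in gene {gene.id}: intron {idx} taken")
            used_introns.add(idx)
            used_exons.add(1 if slot == "start" else n_ex - 2)
            targets[i] = (slot, idx)
        elif etype == "ES":
            cand = [
                k for k in range(1, n_ex - 1)
                if k not in used_exons
                and (k - 1) not in used_introns and k not in used_introns
            ]
            if not cand:
                raise ValueError(f"cannot plant ES in gene {gene.id}: needs a free internal exon")
            k = cand[0]
            used_exons.add(k)
            ir_blocked.update({k - 1, k})
            targets[i] = ("exon", k)
        elif etype in ("IR", "A5SS", "A3SS"):
            blocked = used_introns | (ir_blocked if etype == "IR" else set())
            cand = [j for j in range(n_in) if j not in blocked]
            if etype in ("A5SS", "A3SS"):
                # the exon whose boundary shifts must not belong to a
                # planted ES/OTHER event, or coordinates stop round-tripping
                at_left = (etype == "A5SS") == (gene.strand == "+")
                cand = [
                    j for j in cand
                    if introns[j][1] - introns[j][0] > shift + 2
                    and min(exons[j][1] - exons[j][0], exons[j + 1][1] - exons[j + 1][0]) > shift + 2
                    and (j if at_left else j + 1) not in used_exons
                ]
            if not cand:
                raise ValueError(f"cannot plant {etype} in gene {gene.id}: no free intron")
            used_introns.add(cand[0])
            targets[i] = ("intron", cand[0])
        else:
            raise ValueError(f"unknown event type {etype!r}")

    isoforms: List[TranscriptModel] = []
    truth: List[Tuple[str, str, str, Interval]] = []
    for i, etype in enumerate(event_spec):
        kind, idx = targets[i]
        ex = list(exons)
        if etype == "IR":
            s, e = introns[idx]
            ex[idx : idx + 2] = [(exons[idx][0], exons[idx + 1][1])]
            coords = (s, e)
        elif etype == "ES":
            coords = exons[idx]
            del ex[idx]
        elif etype in ("A5SS", "A3SS"):
            s, e = introns[idx]
            # donor = genomic left on '+', genomic right on '-'
            at_left = (etype == "A5SS") == (gene.strand == "+")
            if at_left:
                ex[idx] = (exons[idx][0], s - shift)
                coords = (s - shift, s)
            else:
                ex[idx + 1] = (e + shift, exons[idx + 1][1])
                coords = (e, e + shift)
        else:  # OTHER: start or end inside a terminal intron
            s, e = introns[idx]
            mid = (s + e) // 2
            if kind == "start":
                ex = [(mid, exons[1][1])] + ex[2:]
            else:
                ex = ex[:-2] + [(exons[-2][0], mid)]
            coords = (s, e)
        iso_id = f"{gene.id}.iso{i + 1}_{etype}"
        isoforms.append(
            TranscriptModel(
                id=iso_id, contig=gene.contig, strand=gene.strand,
                exons=tuple(ex), gene_id=gene.gene_id,
            )
        )
        truth.append((iso_id, etype, gene.contig, coords))
    return isoforms, truth


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def spliced_slice_exons(model: TranscriptModel, s_off: int, e_off: int) -> Tuple[Interval, ...]:
    """Genomic exon chain of a slice [s_off, e_off) of the spliced sequence.

    Offsets are in sense-strand (transcript) coordinates.
    """
    if not (0 <= s_off < e_off <= model.spliced_length):
        raise ValueError("bad spliced slice")
    if model.strand == "-":
        s_off, e_off = model.spliced_length - e_off, model.spliced_length - s_off
    out = []
    walked = 0
    for s, e in model.exons:
        ln = e - s
        lo = max(s_off - walked, 0)
        hi = min(e_off - walked, ln)
        if lo < hi:
            out.append((s + lo, s + hi))
        walked += ln
    return tuple(out)


def _apply_errors(seq: str, p: float, rng, indel_sub_ratio: float = 2.0) -> Tuple[str, int]:
    """i.i.d. per-base errors at rate p; indel:substitution mix 2:1 by
    default (insertions and deletions equally likely)."""
    if p <= 0:
        return seq, 0
    n = len(seq)
    mask = rng.random(n) < p
    n_err = int(mask.sum())
    if n_err == 0:
        return seq, 0
    p_sub = 1.0 / (1.0 + indel_sub_ratio)
    out = []
    kinds = rng.random(n_err)
    bases = rng.integers(0, 4, size=2 * n_err)
    ki = 0
    bi = 0
    letters = "ACGT"
    for i, ch in enumerate(seq):
        if not mask[i]:
            out.append(ch)
            continue
        kind = kinds[ki]
        ki += 1
        if kind < p_sub:  # substitution
            alt = letters[bases[bi] % 4]
            bi += 1
            if alt == ch:
                alt = letters[(letters.index(ch) + 1) % 4]
            out.append(alt)
        elif kind < p_sub + (1 - p_sub) / 2:  # insertion before base
            out.append(letters[bases[bi] % 4])
            bi += 1
            out.append(ch)
        # else deletion: emit nothing
    return "".join(out), n_err


def _sample_class(rng, dist: Mapping[Tuple[bool, bool, bool], float]) -> Tuple[bool, bool, bool]:
    keys = list(dist)
    w = np.array([dist[k] for k in keys], dtype=float)
    w /= w.sum()
    return keys[int(rng.choice(len(keys), p=w))]


def _segment_for(model: TranscriptModel, s_off: int, e_off: int,
                 read_start: int, read_end: int) -> AlignmentSegment:
    chain = spliced_slice_exons(model, s_off, e_off)
    return AlignmentSegment(
        contig=model.contig, start=chain[0][0], end=chain[-1][1],
        strand=model.strand, read_start=read_start, read_end=read_end,
    )


def simulate_long_reads(
    isoforms: Sequence[TranscriptModel],
    genome: SyntheticGenome,
    n_reads: Optional[int] = None,
    p: float = 0.02,
    fl_fraction: float = 0.7,
    truncation_model: Tuple[float, float] = (0.05, 0.30),
    fusion_spec: Sequence[Tuple[str, str]] = (),
    primers: Tuple[str, str] = (PRIMER_5P, PRIMER_3P),
    polya_len: int = 30,
    n_concatemers: int = 0,
    class_distribution: Optional[Mapping[Tuple[bool, bool, bool], float]] = None,
    indel_sub_ratio: float = 2.0,
    seed: int = 0,
    library_id: str = "lib0",
) -> Tuple[List["ReadRecord"], PlantedTruth]:
    """Simulate decorated long reads with planted truth.

    FL reads carry the 5' primer, the transcript, a polyA tail and the 3'
    primer; non-FL reads drop signals per ``class_distribution`` and are
    truncated at any undecorated end by a uniform fraction drawn from
    ``truncation_model``.  Fusion reads concatenate the 5' part of one
    isoform with the 3' part of another (both decorated as FL); concatemer
    reads join two complete decorated cDNAs.  Errors are i.i.d. per base.
    """
    from .models import ReadRecord

    if not isoforms:
        raise ValueError("need at least one isoform to simulate reads")
    if not (0.0 <= p <= 0.2):
        raise ValueError("p must lie in [0, 0.2]")
    if not (0.0 <= fl_fraction <= 1.0):
        raise ValueError("fl_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    primer5, primer3 = primers
    dist = dict(class_distribution or DEFAULT_NONFL_CLASSES)
    by_id = {m.id: m for m in isoforms}
    seqs = {m.id: m.sequence(genome[m.contig]) for m in isoforms}
    truth = PlantedTruth(isoforms=dict(by_id))
    if n_reads is None:
        n_reads = 10 * len(isoforms)

    reads: List[ReadRecord] = []
    polya = "A" * polya_len

    def _emit(read_id, seq, rt):
        noisy, n_err = _apply_errors(seq, p, rng, indel_sub_ratio)
        rt.n_errors = n_err
        rt.read_length = len(noisy)
        reads.append(ReadRecord(read_id=read_id, sequence=noisy,
                                library_id=library_id, error_rate=p))
        truth.reads[read_id] = rt

    # --- ordinary reads ---------------------------------------------------
    iso_ids = [m.id for m in isoforms]
    for i in range(n_reads):
        iso = by_id[iso_ids[int(rng.integers(len(iso_ids)))]]
        base = seqs[iso.id]
        if rng.random() < fl_fraction:
            flags = (True, True, True)
        else:
            flags = _sample_class(rng, dist)
        has5, has3, hasA = flags
        s_off, e_off = 0, len(base)
        lo, hi = truncation_model
        if not has5:
            s_off = int(len(base) * rng.uniform(lo, hi))
        if not hasA:
            e_off = len(base) - int(len(base) * rng.uniform(lo, hi))
        if e_off - s_off < 50:
            s_off, e_off = 0, len(base)
        core = base[s_off:e_off]
        seq = ("" if not has5 else primer5) + core + (polya if hasA else "") + (primer3 if has3 else "")
        model = TranscriptModel(
            id=f"r{i:05d}", contig=iso.contig, strand=iso.strand,
            exons=spliced_slice_exons(iso, s_off, e_off), gene_id=iso.gene_id,
            is_fl=all(flags),
        )
        rt = ReadTruth(
            read_id=f"r{i:05d}", source_isoforms=(iso.id,),
            has_5p=has5, has_3p=has3, has_polya=hasA,
            error_rate=p, n_errors=0, read_length=len(seq),
            segments=(
                _segment_for(iso, s_off, e_off, len(primer5) if has5 else 0,
                             (len(primer5) if has5 else 0) + len(core)),
            ),
            aligned_model=model,
        )
        _emit(f"r{i:05d}", seq, rt)

    # --- fusion reads -----------------------------------------------------
    for fi, (ida, idb) in enumerate(fusion_spec):
        a, b = by_id[ida], by_id[idb]
        sa, sb = seqs[ida], seqs[idb]
        la = max(1, int(0.55 * len(sa)))
        lb = max(1, int(0.45 * len(sb)))
        core = sa[:la] + sb[len(sb) - lb:]
        seq = primer5 + core + polya + primer3
        rid = f"fus{fi:04d}"
        off = len(primer5)
        seg_a = _segment_for(a, 0, la, off, off + la)
        seg_b = _segment_for(b, len(sb) - lb, len(sb), off + la, off + la + lb)
        rt = ReadTruth(
            read_id=rid, source_isoforms=(ida, idb),
            has_5p=True, has_3p=True, has_polya=True,
            error_rate=p, n_errors=0, read_length=len(seq),
            is_fusion=True, segments=(seg_a, seg_b),
        )
        truth.fusions.append((rid, (ida, idb)))
        _emit(rid, seq, rt)

    # --- concatemers --------------------------------------------------------
    for ci in range(n_concatemers):
        ida, idb = (iso_ids[int(rng.integers(len(iso_ids)))] for _ in range(2))
        seq = (primer5 + seqs[ida] + polya + primer3) + (primer5 + seqs[idb] + polya + primer3)
        rid = f"cat{ci:04d}"
        rt = ReadTruth(
            read_id=rid, source_isoforms=(ida, idb),
            has_5p=True, has_3p=True, has_polya=True,
            error_rate=p, n_errors=0, read_length=len(seq),
            is_concatemer=True,
        )
        _emit(rid, seq, rt)

    return reads, truth


def choose_fusion_pairs(
    isoforms: Sequence[TranscriptModel],
    n: int,
    min_distance: int = 100_000,
    seed: int = 0,
) -> List[Tuple[str, str]]:
    """Pick isoform pairs on distinct loci (different contigs, or at least
    ``min_distance`` apart) to serve as fusion templates."""
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(isoforms)))
    pairs: List[Tuple[str, str]] = []
    seen: set = set()
    # first pass pairs each isoform at most once; later passes allow reuse
    # but never repeat an unordered pair
    for reuse in (False, True):
        used: set = set()
        for i in order:
            if len(pairs) >= n:
                return pairs
            if not reuse and i in used:
                continue
            for j in order:
                if i == j or (not reuse and j in used):
                    continue
                a, b = isoforms[i], isoforms[j]
                key = tuple(sorted((a.id, b.id)))
                if key in seen:
                    continue
                if a.contig != b.contig or abs(a.start - b.start) >= min_distance:
                    pairs.append((a.id, b.id))
                    seen.add(key)
                    used.update((i, j))
                    break
    if len(pairs) < n:
        raise GenerationError("not enough distinct locus pairs for fusion_spec")
    return pairs


# ---------------------------------------------------------------------------
# short-read support
# ---------------------------------------------------------------------------

def simulate_short_read_support(
    isoforms: Sequence[TranscriptModel],
    depth: Union[int, Mapping[str, int]] = 30,
    insert_size: int = 300,
    seed: int = 0,
    samples: Sequence[str] = ("S1",),
) -> pd.DataFrame:
    """Per-junction short-read support counts.

    Each junction's count is the sum of the depths of the isoforms that
    contain it (every fragment is assumed to span every junction of its
    isoform, so counts are exact; pass per-isoform depths via a mapping).
    Returns a table with columns sample, contig, start, end, strand, count.
    """
    if isinstance(depth, int):
        if depth < 0:
            raise ValueError("depth must be >= 0")
        depth = {m.id: depth for m in isoforms}
    counts: Dict[Tuple[str, int, int, str], int] = {}
    for m in isoforms:
        for j in m.junctions():
            counts[j] = counts.get(j, 0) + int(depth.get(m.id, 0))
    rows = [
        {"sample": s, "contig": c, "start": a, "end": b, "strand": st, "count": n}
        for s in samples
        for (c, a, b, st), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["sample", "contig", "start", "end", "strand", "count"])


def simulate_locus_links(
    pairs: Iterable[Tuple[str, str]],
    n_pairs: Union[int, Mapping[Tuple[str, str], int]] = 8,
) -> pd.DataFrame:
    """Paired-read locus-link table (columns locus_a, locus_b, n_pairs)
    for the given locus-key pairs, emulating genuinely co-transcribed loci."""
    rows = []
    for a, b in pairs:
        n = n_pairs if isinstance(n_pairs, int) else n_pairs.get((a, b), n_pairs.get((b, a), 0))
        rows.append({"locus_a": a, "locus_b": b, "n_pairs": int(n)})
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "n_pairs"])
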