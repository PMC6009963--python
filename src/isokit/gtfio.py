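"""File I/O: FASTA (biopython), GTF (gffutils for parsing), SAM (pysam), TSV.

Internal coordinates are 0-based half-open; GTF emission converts to the
format's 1-based closed convention and parsing converts back.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignmentSegment, TranscriptAlignment, TranscriptModel

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gtf",
    "read_gtf",
    "alignments_from_sam",
]


def write_fasta(records: Iterable[Tuple[str, str]], path: str) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_gtf(models: Sequence[TranscriptModel], path: str, source: str = "isokit") -> None:
    """Emit transcript/exon (and CDS, when present) GTF lines, 1-based closed."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.id}";'
            fh.write(
                "\t".join(
                    [m.contig, source, "transcript", str(m.start + 1), str(m.end),
                     ".", m.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(
                        [m.contig, source, "exon", str(s + 1), str(e), ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )
            if m.cds is not None:
                cs, ce = m.cds
                fh.write(
                    "\t".join(
                        [m.contig, source, "CDS", str(cs + 1), str(ce), ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_gtf(path: str) -> List[TranscriptModel]:
    """Parse a GTF/GFF3 file into transcript models (gffutils-backed)."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: Dict[str, List] = {}
    cds: Dict[str, Tuple[int, int]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta[tid] = (feat.seqid, feat.strand, gid)
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            lo, hi = cds.get(tid, iv)
            cds[tid] = (min(lo, iv[0]), max(hi, iv[1]))
    models = []
    for tid, ivs in exons.items():
        contig, strand, gid = meta[tid]
        models.append(
            TranscriptModel(
                id=tid,
                contig=contig,
                strand=strand,
                exons=tuple(sorted(ivs)),
                gene_id=gid,
                cds=cds.get(tid),
            )
        )
    return models


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M, I, S, =, X
_ALIGNED_OPS = {0, 7, 8}            # M, =, X


def _segment_from_read(rec: "pysam.AlignedSegment") -> AlignmentSegment:
    qstart = rec.query_alignment_start
    qend = rec.query_alignment_end
    if rec.is_reverse:
        # express read coordinates on the original (sequenced) strand
        full = rec.infer_read_length() or (qend + (rec.query_length - qend))
        qstart, qend = full - qend, full - qstart
    return AlignmentSegment(
        contig=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        read_start=qstart,
        read_end=qend,
    )


def alignments_from_sam(path: str) -> List[TranscriptAlignment]:
    """Read spliced alignments from SAM/BAM, one TranscriptAlignment per read.

    The primary alignment supplies the exon blocks; supplementary records of
    the same read become extra segments (split alignment).  ``K`` is taken
    from the NM tag (mismatches + indel bases), ``L`` from the aligned
    (M/=/X) base count.
    """
    primaries: Dict[str, TranscriptAlignment] = {}
    extra_segments: Dict[str, List[AlignmentSegment]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            name = rec.query_name
            if rec.is_supplementary:
                extra_segments.setdefault(name, []).append(_segment_from_read(rec))
                continue
            blocks: List[Tuple[int, int]] = []
            pos = rec.reference_start
            L = 0
            for op, n in rec.cigartuples or ():
                if op in _ALIGNED_OPS:
                    if blocks and blocks[-1][1] == pos:
                        blocks[-1] = (blocks[-1][0], pos + n)
                    else:
                        blocks.append((pos, pos + n))
                    pos += n
                    L += n
                elif op in (2,):  # D: reference advance, merge into block
                    if blocks and blocks[-1][1] == pos:
                        blocks[-1] = (blocks[-1][0], pos + n)
                    else:
                        blocks.append((pos, pos + n))
                    pos += n
                elif op == 3:  # N: intron
                    pos += n
            K = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            read_len = rec.infer_read_length() or rec.query_length
            primaries[name] = TranscriptAlignment(
                read_id=name,
                contig=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                blocks=tuple(blocks),
                L=L,
                K=min(K, L),
                read_length=read_len,
                segments=(_segment_from_read(rec),),
            )
    for name, segs in extra_segments.items():
        if name in primaries:
            aln = primaries[name]
            aln.segments = tuple(sorted(aln.segments + tuple(segs), key=lambda s: s.read_start))
    return list(primaries.values())
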