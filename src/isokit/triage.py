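"""Full-length read triage: length filter, 5'/3'/polyA signal detection,
and artificial-concatemer flagging.

A read is full length (FL) when the 5' primer, the 3' primer, and a polyA
tail are all present; the seven other presence/absence combinations form
the non-FL signal classes.  Primers are matched approximately (edlib
edit distance) inside a terminal window so that detection tolerates raw
long-read error rates; a primer hit in the read *interior* marks a
putative artificial concatemer, the library artifact that joins two cDNAs
in one read.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple

import edlib

from .models import ReadRecord, TriageResult, revcomp

__all__ = [
    "filter_short_reads",
    "classify_signals",
    "flag_concatemer",
    "triage_reads",
]

TERMINAL_WINDOW = 100


def _default_max_mismatch(primer: str) -> int:
    # tolerate raw-read error rates on a short primer
    return math.ceil(0.2 * len(primer))


def filter_short_reads(
    reads: Sequence[ReadRecord], min_len: int = 300
) -> Tuple[List[ReadRecord], List[ReadRecord]]:
    """Partition reads into (kept, removed) by the strict length rule
    ``length > min_len``."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in reads if len(r) > min_len]
    removed = [r for r in reads if len(r) <= min_len]
    return kept, removed


def _find_primer(seq: str, primer: str, max_mismatch: int) -> Optional[Tuple[int, int]]:
    """Best approximate occurrence (start, end) of primer in seq, or None."""
    if not seq:
        return None
    res = edlib.align(primer, seq, mode="HW", task="locations", k=max_mismatch)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    return (s if s is not None else 0, e + 1)


def _polya_run(seq: str, end_pos: int, min_polya: int, max_nona_per10: int = 1) -> bool:
    """Is there a >= min_polya A-rich run ending at (or just before) end_pos?

    Allows ``max_nona_per10`` non-A bases per 10 nt of run (sequencing
    errors strike the tail too).
    """
    window = seq[max(0, end_pos - min_polya) : end_pos]
    if len(window) < min_polya:
        return False
    allowed = max_nona_per10 * (min_polya // 10)
    return sum(ch != "A" for ch in window) <= allowed


def _classify_one_orientation(
    seq: str,
    primer5: str,
    primer3: str,
    min_polya: int,
    max_mismatch5: int,
    max_mismatch3: int,
    window: int,
) -> Tuple[bool, bool, bool]:
    head = seq[: window + len(primer5)]
    tail_start = max(0, len(seq) - (window + len(primer3)))
    tail = seq[tail_start:]
    hit5 = _find_primer(head, primer5, max_mismatch5)
    hit3 = _find_primer(tail, primer3, max_mismatch3)
    has5 = hit5 is not None
    has3 = hit3 is not None
    if has3:
        polya_end = tail_start + hit3[0]
        # small slack between tail end and primer start
        hasA = any(_polya_run(seq, polya_end - d, min_polya) for d in (0, 2, 5))
    else:
        hasA = _polya_run(seq, len(seq), min_polya) or any(
            _polya_run(seq, len(seq) - d, min_polya) for d in (5, 10, 20)
        )
    return has5, has3, hasA


def classify_signals(
    read: ReadRecord,
    primer5: str,
    primer3: str,
    min_polya: int = 20,
    max_mismatch: Optional[int] = None,
    window: int = TERMINAL_WINDOW,
    min_len: int = 300,
) -> TriageResult:
    """Classify one read into its 8-way signal class.

    The 5' primer is sought near the read start, the 3' primer near the
    read end (each within ``window`` bp, allowing ``max_mismatch`` edits,
    default ceil(0.2 x primer length)), and a >= ``min_polya`` A run
    immediately 5' of the 3' primer.  Both orientations are tried; the one
    yielding more signals wins, ties going to forward.
    """
    if not primer5 or not primer3:
        raise ValueError("primers must be non-empty")
    mm5 = max_mismatch if max_mismatch is not None else _default_max_mismatch(primer5)
    mm3 = max_mismatch if max_mismatch is not None else _default_max_mismatch(primer3)
    fwd = _classify_one_orientation(read.sequence, primer5, primer3, min_polya, mm5, mm3, window)
    rev = _classify_one_orientation(
        revcomp(read.sequence), primer5, primer3, min_polya, mm5, mm3, window
    )
    flags, orient = (fwd, "+") if sum(fwd) >= sum(rev) else (rev, "-")
    return TriageResult(
        read_id=read.read_id,
        has_5p=flags[0],
        has_3p=flags[1],
        has_polya=flags[2],
        length=len(read),
        length_pass=len(read) > min_len,
        orientation=orient,
    )


def flag_concatemer(
    read: ReadRecord,
    primer5: str,
    primer3: str,
    max_mismatch: Optional[int] = None,
    window: int = TERMINAL_WINDOW,
) -> bool:
    """True iff a primer (either one, either strand) occurs in the read
    interior, outside both terminal windows."""
    seq = read.sequence
    lo = window + max(len(primer5), len(primer3))
    hi = len(seq) - lo
    if hi - lo < min(len(primer5), len(primer3)):
        return False
    interior = seq[lo:hi]
    for primer in (primer5, primer3, revcomp(primer5), revcomp(primer3)):
        mm = max_mismatch if max_mismatch is not None else _default_max_mismatch(primer)
        if _find_primer(interior, primer, mm) is not None:
            return True
    return False


def triage_reads(
    reads: Iterable[ReadRecord],
    primer5: str,
    primer3: str,
    min_len: int = 300,
    min_polya: int = 20,
    max_mismatch: Optional[int] = None,
    window: int = TERMINAL_WINDOW,
) -> List[TriageResult]:
    """Run signal classification, the length filter, and concatemer
    flagging over a read set."""
    out = []
    for r in reads:
        res = classify_signals(
            r, primer5, primer3, min_polya=min_polya, max_mismatch=max_mismatch,
            window=window, min_len=min_len,
        )
        res.concatemer = flag_concatemer(r, primer5, primer3, max_mismatch=max_mismatch, window=window)
        out.append(res)
    return out
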