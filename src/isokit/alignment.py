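"""Alignment quality filtering and the statistical mis-mapping test.

The model: sequencing errors strike independently at a fixed per-library
per-base rate ``p``, so the error count ``K`` over an aligned length ``L``
is Binomial(L, p).  An alignment to the *correct* locus should therefore
show K near L*p; an alignment to a merely homologous locus accumulates the
extra divergence between the loci on top of the sequencing errors.  The
tail probability

    P(errors >= K)  ~  1 - Phi((K - L*p) / sqrt(L*p*(1-p)))

(the de Moivre-Laplace normal approximation) quantifies how surprising an
observed K is under correct mapping, and the decision rule flags an
alignment as mis-mapped when K exceeds L*(p + margin) with margin 0.03.

Note the normal tail deviates from the exact binomial survival function by
up to ~0.2/sigma (sigma = sqrt(L*p*(1-p))) near the distribution mode, so
for short alignments at low error rates the approximation is crude; an
optional continuity correction roughly halves the gap.  The decision rule
itself only depends on the fixed threshold, not on the approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from scipy.stats import norm

from .models import MismapVerdict, TranscriptAlignment

__all__ = [
    "compute_identity_coverage",
    "filter_high_quality",
    "select_best_alignment",
    "mismap_pvalue",
    "mismap_flag",
    "FprFnrResult",
    "evaluate_fpr_fnr",
]


def compute_identity_coverage(aln: TranscriptAlignment) -> Tuple[float, float]:
    """Alignment identity ``(L - K)/L`` and read coverage ``L / read_length``."""
    if aln.L == 0:
        raise ValueError("alignment has zero aligned length")
    return aln.identity, aln.coverage


def filter_high_quality(
    alns: Iterable[TranscriptAlignment],
    min_identity: float = 0.90,
    min_coverage: float = 0.85,
) -> List[TranscriptAlignment]:
    """Keep alignments with at least ``min_identity`` identity *and*
    ``min_coverage`` read coverage (both inclusive)."""
    if not (0.0 <= min_identity <= 1.0 and 0.0 <= min_coverage <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    return [a for a in alns if a.identity >= min_identity and a.coverage >= min_coverage]


def select_best_alignment(alns: Sequence[TranscriptAlignment]) -> TranscriptAlignment:
    """The single best alignment of one read: maximal identity x coverage,
    exact ties broken by lexicographically smallest (contig, start)."""
    if not alns:
        raise ValueError("no alignments given")
    return min(alns, key=lambda a: (-(a.identity * a.coverage), a.contig, a.start))


def mismap_pvalue(K: int, L: int, p: float, continuity_correction: bool = False) -> float:
    """Normal-tail probability that a correctly mapped read of aligned
    length ``L`` shows at least ``K`` errors at per-base error rate ``p``.

    Monotone non-increasing in K; equals 0.5 at K = L*p (without the
    optional continuity correction).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly inside (0, 1): variance degenerates at 0 and 1")
    if not (0 <= K <= L):
        raise ValueError("need 0 <= K <= L")
    k = K - 0.5 if continuity_correction else K
    z = (k - L * p) / math.sqrt(L * p * (1.0 - p))
    return float(norm.sf(z))


def mismap_flag(
    K: int,
    L: int,
    p: float,
    margin: float = 0.03,
    read_id: str = "",
) -> MismapVerdict:
    """Apply the fixed-margin decision rule: flag iff K > L*(p + margin)."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    pv = mismap_pvalue(K, L, p)
    threshold = L * (p + margin)
    return MismapVerdict(
        read_id=read_id,
        K=K,
        L=L,
        p=p,
        pvalue=pv,
        threshold_K=threshold,
        flagged=K > threshold,
    )


@dataclass
class FprFnrResult:
    """Both orientations of the 2x2 confusion table.

    With "positive" = flagged as mis-mapped (truth positive = wrong locus):
    ``fpr_flagging`` is the fraction of correct-locus alignments flagged and
    ``fnr_flagging`` the fraction of wrong-locus alignments left unflagged.
    The opposite orientation ("positive" = accepted as correctly mapped)
    simply swaps the two labels and is exposed for convenience.
    """

    n_correct: int
    n_wrong: int
    fpr_flagging: float
    fnr_flagging: float

    @property
    def fpr_acceptance(self) -> float:
        return self.fnr_flagging

    @property
    def fnr_acceptance(self) -> float:
        return self.fpr_flagging


def evaluate_fpr_fnr(
    labelled: Iterable[Tuple[bool, bool]],
) -> FprFnrResult:
    """Evaluate the decision rule against truth labels.

    Parameters
    ----------
    labelled : iterable of (flagged, correct_locus)
        One entry per alignment: whether the rule flagged it, and whether it
        truly maps to the correct locus.
    """
    n_correct = n_wrong = flagged_correct = unflagged_wrong = 0
    for flagged, correct in labelled:
        if flagged is None or correct is None:
            raise ValueError("every alignment needs a flag and a truth label")
        if correct:
            n_correct += 1
            flagged_correct += bool(flagged)
        else:
            n_wrong += 1
            unflagged_wrong += not flagged
    if n_correct == 0 and n_wrong == 0:
        raise ValueError("no labelled alignments")
    return FprFnrResult(
        n_correct=n_correct,
        n_wrong=n_wrong,
        fpr_flagging=flagged_correct / n_correct if n_correct else 0.0,
        fnr_flagging=unflagged_wrong / n_wrong if n_wrong else 0.0,
    )
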