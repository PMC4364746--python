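"""Per-site Shannon entropy of aligned read stacks: MIH, MIH5, MIH3.

The isoform-heterogeneity score of a mature miRNA is the mean per-site
Shannon entropy (base 2) of the multiplicity-weighted symbol distribution
over a 5-letter alphabet {A, U, G, C, gap} inside the canonical mature
region extended by 4 nt on each side::

    MIH = (1/L) * sum_i H_i,    H_i = -sum_j p_j(i) * log2 p_j(i)

Every read in the stack contributes at every window site — its base when
it covers the site, the gap symbol otherwise — so each column's depth
equals the stack's total read count.  MIH5 and MIH3 apply the same average
to the 9 positions centered on the canonical 5' and 3' ends, isolating
cleavage-site heterogeneity at each end.

A read of count c weighs c times (abundances, not unique sequences, carry
the expression structure).  N bases contribute to the gap symbol.  No
pseudocounts: frequencies are the raw observed ones, with 0*log2(0) = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cohort import classify_arm
from .errors import ValidationError
from .types import (
    GAP,
    SYMBOLS,
    EntropyResult,
    MatureAnnotation,
    PrecursorRecord,
    ReadStack,
)

logger = logging.getLogger(__name__)

MAX_ENTROPY = math.log2(len(SYMBOLS))  # log2(5), the 5-symbol ceiling
FLANK = 4  # nt added on each side of the canonical mature region
END_WINDOW = 2 * FLANK + 1  # 9: the end site plus +-4 nt

_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}
_GAP_INDEX = _SYM_INDEX[GAP]


@dataclass(frozen=True)
class Window:
    """A half-open run of precursor coordinates an entropy average runs over."""

    lo: int
    hi: int
    clipped: bool = False

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValidationError(f"empty window [{self.lo}, {self.hi})")

    @property
    def length(self) -> int:
        return self.hi - self.lo


@dataclass(frozen=True)
class SiteDistribution:
    """Multiplicity-weighted symbol tallies at one precursor coordinate.

    ``counts`` follows the SYMBOLS order (A, U, G, C, gap); ``depth`` always
    equals the stack's total count because uncovered reads tally as gaps.
    """

    position: int
    counts: tuple[int, ...]
    depth: int


def select_windows(
    mature: MatureAnnotation, precursor_length: int
) -> tuple[Window, Window, Window]:
    """Windows for MIH (mature +-4), MIH5 (5' end +-4) and MIH3 (3' end +-4).

    Nominal spans are ``[start-4, end+4)``, ``[start-4, start+5)`` and
    ``[end-5, end+4)``; each is intersected with the precursor and flagged
    ``clipped`` when truncated.  The effective (possibly shrunken) length is
    what later divides the entropy sum — averaging over sites that do not
    exist would deflate the score.
    """
    if mature.end > precursor_length:
        raise ValidationError(
            f"mature {mature.mature_name!r} ends at {mature.end}, beyond the "
            f"{precursor_length}-nt precursor"
        )

    def clip(lo: int, hi: int) -> Window:
        c_lo, c_hi = max(lo, 0), min(hi, precursor_length)
        if c_lo >= c_hi:
            raise ValidationError(
                f"window [{lo}, {hi}) empty after clipping to "
                f"[0, {precursor_length})"
            )
        return Window(c_lo, c_hi, clipped=(c_lo != lo or c_hi != hi))

    full = clip(mature.start - FLANK, mature.end + FLANK)
    w5 = clip(mature.start - FLANK, mature.start + FLANK + 1)
    w3 = clip(mature.end - FLANK - 1, mature.end + FLANK)
    for name, w in (("full", full), ("5'", w5), ("3'", w3)):
        if w.clipped:
            logger.warning(
                "%s window of %s clipped to [%d, %d)",
                name,
                mature.mature_name,
                w.lo,
                w.hi,
            )
    return full, w5, w3


def site_distribution(stack: ReadStack, position: int) -> SiteDistribution:
    """Tally the 5-symbol distribution at one precursor coordinate.

    Each read contributes its count to its base at the site when it covers
    it, and to the gap symbol when it does not (or carries an N there).
    """
    if not stack.reads:
        raise ValidationError(f"stack {stack.precursor_id!r} is empty")
    counts = [0] * len(SYMBOLS)
    for read in stack.reads:
        base = read.base_at(position)
        idx = _SYM_INDEX.get(base, _GAP_INDEX) if base is not None else _GAP_INDEX
        if base is not None and base not in _SYM_INDEX:
            logger.warning(
                "read at %d on %s: symbol %r at position %d treated as gap",
                read.start,
                stack.precursor_id,
                base,
                position,
            )
        counts[idx] += read.count
    return SiteDistribution(position, tuple(counts), sum(counts))


def site_entropy(dist: SiteDistribution) -> float:
    """Shannon entropy (bits) of one site distribution; 0*log2(0) = 0."""
    if dist.depth <= 0:
        raise ValidationError(f"site {dist.position}: zero depth")
    p = np.asarray(dist.counts, dtype=float) / dist.depth
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _window_entropy_sum(stack: ReadStack, window: Window) -> float:
    """Sum of site entropies across a window, vectorized over columns.

    Builds the 5 x L count matrix in one pass over unique reads: the gap row
    starts at total_count per column and each covered base moves its count
    out of the gap row.
    """
    total = stack.total_count
    L = window.length
    counts = np.zeros((len(SYMBOLS), L), dtype=np.int64)
    counts[_GAP_INDEX, :] = total
    for read in stack.reads:
        lo = max(window.lo, read.start)
        hi = min(window.hi, read.end)
        for pos in range(lo, hi):
            sym = read.sequence[pos - read.start]
            idx = _SYM_INDEX.get(sym, _GAP_INDEX)
            if idx != _GAP_INDEX:
                counts[idx, pos - window.lo] += read.count
                counts[_GAP_INDEX, pos - window.lo] -= read.count
    p = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return float(-terms.sum())


def compute_mih(
    stack: ReadStack, mature: MatureAnnotation, precursor: PrecursorRecord
) -> EntropyResult:
    """Compute MIH, MIH5 and MIH3 for one mature miRNA over its read stack.

    Raises
    ------
    ValidationError
        Empty stack, or stack/annotation/precursor ids that disagree.
    """
    if not stack.reads:
        raise ValidationError(f"stack {stack.precursor_id!r} is empty")
    if stack.precursor_id != mature.precursor_id:
        raise ValidationError(
            f"stack is on {stack.precursor_id!r} but mature "
            f"{mature.mature_name!r} is on {mature.precursor_id!r}"
        )
    mature.validate_against(precursor)

    full, w5, w3 = select_windows(mature, len(precursor))
    mih = _window_entropy_sum(stack, full) / full.length
    mih5 = _window_entropy_sum(stack, w5) / w5.length
    mih3 = _window_entropy_sum(stack, w3) / w3.length

    return EntropyResult(
        mature_name=mature.mature_name,
        precursor_id=mature.precursor_id,
        arm=classify_arm(mature.mature_name),
        mih=mih,
        mih5=mih5,
        mih3=mih3,
        total_count=stack.total_count,
        L=full.length,
        L5=w5.length,
        L3=w3.length,
        precursor_length=len(precursor),
        mfe=precursor.mfe,
    )
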