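"""Cohort assembly: depth filtering, arm classification and arm pairing.

The inclusion filter keeps a mature miRNA only when its read stack holds
strictly more than 50 and strictly fewer than 10000 reads: shallow stacks
systematically underestimate isoform heterogeneity, and very deep ones are
suspect for PCR amplification bias.  Arm identity comes from the mature
name alone (a ``-5p`` / ``-3p`` suffix), matching how public annotations
distinguish two-arm from single-arm products.
"""

from __future__ import annotations

import logging
import re

from .errors import ConfigurationError, ValidationError
from .types import ArmPair, EntropyResult, MatureAnnotation, ReadStack

logger = logging.getLogger(__name__)

MIN_COUNT_DEFAULT = 50
MAX_COUNT_DEFAULT = 10000
ISOMIR_FLANK = 4  # a read is an isomiR of a mature when both ends fall within +-4 nt

_ARM_SUFFIX = re.compile(r"[-.](5p|3p)$", re.IGNORECASE)


def assign_reads_to_mature(
    stack: ReadStack, mature: MatureAnnotation, flank: int = ISOMIR_FLANK
) -> ReadStack:
    """Subset a precursor stack to the isomiRs of one mature miRNA.

    A read qualifies when its start lies within ``flank`` nt of the
    canonical 5' end and its end within ``flank`` nt of the canonical
    3' end.  Reads from the opposite arm (or elsewhere on the hairpin)
    are excluded so they cannot flood the entropy windows with gaps.
    """
    reads = [
        r
        for r in stack.reads
        if abs(r.start - mature.start) <= flank and abs(r.end - mature.end) <= flank
    ]
    return ReadStack(stack.precursor_id, reads)


def filter_by_depth(
    stacks: list[ReadStack],
    min_ex: int = MIN_COUNT_DEFAULT,
    max_ex: int = MAX_COUNT_DEFAULT,
) -> list[ReadStack]:
    """Keep stacks with ``min_ex < total_count < max_ex`` (both bounds strict).

    Order is preserved; rejections are logged with their reason.
    """
    if min_ex >= max_ex:
        raise ConfigurationError(
            f"min count {min_ex} must be below max count {max_ex}"
        )
    kept = []
    for stack in stacks:
        n = stack.total_count
        if n <= min_ex:
            logger.info("%s rejected: %d reads <= %d", stack.precursor_id, n, min_ex)
        elif n >= max_ex:
            logger.info("%s rejected: %d reads >= %d", stack.precursor_id, n, max_ex)
        else:
            kept.append(stack)
    return kept


def classify_arm(mature_name: str) -> str:
    """Map a mature name to ``"5p"``, ``"3p"`` or ``"single"``.

    Only the terminal ``-5p`` / ``-3p`` (or ``.5p`` / ``.3p``) token is
    inspected, case-insensitively; anything else is a single-arm product.
    Total on non-empty strings — never raises.
    """
    m = _ARM_SUFFIX.search(mature_name.strip())
    return m.group(1).lower() if m else "single"


def pair_arms(results: list[EntropyResult]) -> list[ArmPair]:
    """Pair the 5p and 3p products of each precursor for high/low comparison.

    Precursors lacking either arm are skipped (logged).  Two results
    claiming the same (precursor, arm) are a data error.
    """
    by_precursor: dict[str, dict[str, EntropyResult]] = {}
    order: list[str] = []
    for r in results:
        if r.arm not in ("5p", "3p"):
            continue
        arms = by_precursor.setdefault(r.precursor_id, {})
        if r.precursor_id not in order:
            order.append(r.precursor_id)
        if r.arm in arms:
            raise ValidationError(
                f"two {r.arm} results for precursor {r.precursor_id!r} "
                f"({arms[r.arm].mature_name!r} and {r.mature_name!r})"
            )
        arms[r.arm] = r

    pairs = []
    for pid in order:
        arms = by_precursor[pid]
        if "5p" in arms and "3p" in arms:
            pairs.append(ArmPair(pid, arms["5p"], arms["3p"]))
        else:
            logger.info("%s skipped: only the %s arm present", pid, next(iter(arms)))
    return pairs
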