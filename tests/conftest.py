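"""Shared fixtures and independent oracles.

The brute-force entropy oracle here deliberately shares no code with the
package: it expands every read to unit copies, materializes the full
character matrix over a window, and tallies columns with
``collections.Counter``.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from mirentropy import (
    AlignedRead,
    MatureAnnotation,
    PrecursorRecord,
    ReadStack,
)

RNA = "AUGC"


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_window_entropy(stack: ReadStack, lo: int, hi: int) -> float:
    """Mean per-column Shannon entropy by explicit unit-read expansion."""
    rows = []
    for read in stack.reads:
        for _ in range(read.count):  # unit expansion
            row = []
            for pos in range(lo, hi):
                if read.start <= pos < read.start + len(read.sequence):
                    base = read.sequence[pos - read.start]
                    row.append(base if base in RNA else "-")
                else:
                    row.append("-")
            rows.append(row)
    entropies = []
    for col in zip(*rows):
        tally = Counter(col)
        n = sum(tally.values())
        h = -sum((c / n) * math.log2(c / n) for c in tally.values())
        entropies.append(h)
    return sum(entropies) / len(entropies)


def brute_force_mih(stack, mature, precursor_length):
    """(mih, mih5, mih3) via the unit-expansion oracle with clipped windows."""
    full = (max(mature.start - 4, 0), min(mature.end + 4, precursor_length))
    w5 = (max(mature.start - 4, 0), min(mature.start + 5, precursor_length))
    w3 = (max(mature.end - 5, 0), min(mature.end + 4, precursor_length))
    return tuple(brute_force_window_entropy(stack, lo, hi) for lo, hi in (full, w5, w3))


# ---------------------------------------------------------------------------
# random stack construction
# ---------------------------------------------------------------------------

def random_case(rng: np.random.Generator, max_reads: int = 6, max_len: int = 40):
    """A random (stack, mature, precursor) triple on a <=40 nt precursor."""
    plen = int(rng.integers(30, max_len + 1))
    seq = "".join(rng.choice(list(RNA), size=plen))
    precursor = PrecursorRecord(f"p{rng.integers(1e6)}", seq)
    m_start = int(rng.integers(4, 8))
    m_len = int(rng.integers(16, min(22, plen - m_start - 4) + 1))
    mature = MatureAnnotation(precursor.precursor_id, "mat-x", m_start, m_start + m_len)
    n_reads = int(rng.integers(1, max_reads + 1))
    reads = []
    for _ in range(n_reads):
        start = int(rng.integers(0, plen - 12))
        length = int(rng.integers(10, min(26, plen - start) + 1))
        read_seq = list(seq[start : start + length])
        # sprinkle substitutions so columns genuinely mix bases
        for j in range(len(read_seq)):
            if rng.random() < 0.1:
                read_seq[j] = RNA[rng.integers(4)]
        reads.append(AlignedRead("".join(read_seq), start, int(rng.integers(1, 50))))
    return ReadStack(precursor.precursor_id, reads).merged(), mature, precursor


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def micro_case():
    """The 24-nt worked example: two reads shifted by one position."""
    precursor = PrecursorRecord("p1", "ACGUACGUACGUACGUACGUACGU")
    mature = MatureAnnotation("p1", "m1", 4, 14)
    stack = ReadStack(
        "p1",
        [
            AlignedRead(precursor.sequence[4:14], 4, 2),
            AlignedRead(precursor.sequence[5:15], 5, 2),
        ],
    )
    return stack, mature, precursor
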