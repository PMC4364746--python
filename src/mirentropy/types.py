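"""Domain containers shared by every module.

Coordinates are 0-based, half-open everywhere: a mature miRNA annotated
``start=10, end=32`` occupies precursor positions 10..31 inclusive.  Reads
are gapless placements on a precursor; a read may start before position 0 or
run past the precursor 3' end (non-templated tailing), in which case the
overhanging bases exist only in the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError

logger = logging.getLogger(__name__)

RNA_ALPHABET = ("A", "U", "G", "C")
GAP = "-"
#: the 5-symbol alphabet over which per-site distributions are formed
SYMBOLS = RNA_ALPHABET + (GAP,)


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class PrecursorRecord:
    """A pre-miRNA hairpin sequence, optionally with its folding energy.

    Parameters
    ----------
    precursor_id : str
        Identifier (first whitespace-delimited FASTA header token).
    sequence : str
        RNA sequence over {A, U, G, C, N}; DNA input is normalized.
    mfe : float, optional
        Minimum free energy of the predicted secondary structure
        (kcal/mol, typically negative).  Taken as given, never computed.
    """

    precursor_id: str
    sequence: str
    mfe: Optional[float] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"precursor {self.precursor_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """Canonical mature miRNA coordinates on its precursor."""

    precursor_id: str
    mature_name: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    canonical_seq: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"mature {self.mature_name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.end - self.start < 16:
            # real mature miRNAs are ~19-24 nt; shorter annotations are suspect
            # but legal (toy stacks, truncated precursors), so warn rather than refuse
            logger.warning(
                "mature %r is only %d nt; real mature miRNAs are ~19-24 nt",
                self.mature_name,
                self.end - self.start,
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate_against(self, precursor: PrecursorRecord) -> None:
        """Check coordinates (and canonical_seq, when present) against the precursor."""
        if self.precursor_id != precursor.precursor_id:
            raise ValidationError(
                f"mature {self.mature_name!r} annotated on {self.precursor_id!r}, "
                f"not {precursor.precursor_id!r}"
            )
        if self.end > len(precursor):
            raise ValidationError(
                f"mature {self.mature_name!r}: end {self.end} beyond precursor "
                f"length {len(precursor)}"
            )
        if self.canonical_seq is not None:
            expected = precursor.sequence[self.start : self.end]
            if normalize_rna(self.canonical_seq) != expected:
                raise ValidationError(
                    f"mature {self.mature_name!r}: canonical_seq does not match "
                    f"precursor[{self.start}:{self.end}]"
                )


@dataclass(frozen=True)
class AlignedRead:
    """One unique read placed on a precursor with a multiplicity count.

    ``start`` may be negative and ``start + len(sequence)`` may exceed the
    precursor length; overhanging bases exist only in the read.
    """

    sequence: str
    start: int
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValidationError(f"read at {self.start}: count {self.count} < 1")
        if not self.sequence:
            raise ValidationError(f"read at {self.start}: empty sequence")

    @property
    def end(self) -> int:
        """0-based exclusive end on the precursor coordinate system."""
        return self.start + len(self.sequence)

    def base_at(self, position: int) -> Optional[str]:
        """Base carried at a precursor coordinate, or None when not covered."""
        if self.start <= position < self.end:
            return self.sequence[position - self.start]
        return None


@dataclass
class ReadStack:
    """All aligned reads for one precursor — the unit of entropy computation."""

    precursor_id: str
    reads: list[AlignedRead] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)

    def merged(self) -> "ReadStack":
        """Collapse duplicate (sequence, start) placements by summing counts."""
        acc: dict[tuple[str, int], int] = {}
        for r in self.reads:
            key = (r.sequence, r.start)
            acc[key] = acc.get(key, 0) + r.count
        reads = [AlignedRead(seq, start, c) for (seq, start), c in acc.items()]
        return ReadStack(self.precursor_id, reads)


@dataclass
class EntropyResult:
    """MIH / MIH5 / MIH3 for one mature miRNA, plus provenance."""

    mature_name: str
    precursor_id: str
    arm: str  # "5p" | "3p" | "single"
    mih: float
    mih5: float
    mih3: float
    total_count: int
    L: int
    L5: int
    L3: int
    precursor_length: int
    mfe: Optional[float] = None


@dataclass
class ArmPair:
    """The 5p and 3p products of one precursor, ordered by MIH."""

    precursor_id: str
    result_5p: EntropyResult
    result_3p: EntropyResult

    @property
    def high_mih(self) -> float:
        return max(self.result_5p.mih, self.result_3p.mih)

    @property
    def low_mih(self) -> float:
        return min(self.result_5p.mih, self.result_3p.mih)
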