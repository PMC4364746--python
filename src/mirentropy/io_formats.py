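"""Readers and writers for every external representation.

Dialects
--------
* precursor FASTA — standard FASTA; DNA ``T`` is normalized to ``U``; the
  record id is the first whitespace-delimited header token.
* mature-annotation TSV — columns ``precursor_id, mature_name, start, end``
  (optional ``canonical_seq``); coordinates are 0-based half-open.
* read-stack TSV — columns ``precursor_id, read_seq, start, count``.
* MFE TSV — columns ``precursor_id, mfe`` (kcal/mol, an input, never computed).
* annotation-set TSV — ``term_name <TAB> comma-separated precursor_ids``.
* miRBase-style alignment block — a precursor line followed by read lines
  padded with ``-`` or ``.`` outside the read span, each carrying a trailing
  count token (best-effort: miRBase pages vary).

All TSV dialects are tab-separated UTF-8; lines starting with ``#`` are
ignored.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

from .errors import FormatError, ValidationError
from .types import (
    AlignedRead,
    EntropyResult,
    MatureAnnotation,
    PrecursorRecord,
    ReadStack,
    normalize_rna,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_VALID_RNA = re.compile(r"^[ACGUN]+$")
_FILLERS = "-."


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_precursor_fasta(path: PathLike) -> list[PrecursorRecord]:
    """Read precursor hairpins from FASTA, normalizing DNA to RNA.

    Raises
    ------
    FormatError
        If the file holds no records, or a sequence contains a letter
        outside {A, C, G, U, T, N} (case-insensitive).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_rna(str(rec.seq))
        if not seq:
            raise FormatError(f"precursor {rec.id!r}: empty sequence")
        if not _VALID_RNA.match(seq):
            bad = sorted(set(seq) - set("ACGUN"))
            raise FormatError(
                f"precursor {rec.id!r}: invalid symbol(s) {''.join(bad)!r}"
            )
        records.append(PrecursorRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# generic TSV plumbing
# ---------------------------------------------------------------------------

def _tsv_rows(path: PathLike, required: Iterable[str]):
    """Yield (line_number, dict) rows from a '#'-commented TSV with a header."""
    required = list(required)
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [
            (i, line)
            for i, line in enumerate(fh, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0][1].rstrip("\n").split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; header is {header}")
    for lineno, line in lines[1:]:
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        yield lineno, dict(zip(header, fields))


def _parse_int(value: str, what: str, path: PathLike, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {what} {value!r}") from None


# ---------------------------------------------------------------------------
# annotations / MFE / read stacks
# ---------------------------------------------------------------------------

def read_mature_annotations(path: PathLike) -> list[MatureAnnotation]:
    """Read mature annotations (0-based half-open coordinates)."""
    out = []
    for lineno, row in _tsv_rows(
        path, ["precursor_id", "mature_name", "start", "end"]
    ):
        start = _parse_int(row["start"], "start", path, lineno)
        end = _parse_int(row["end"], "end", path, lineno)
        canonical = row.get("canonical_seq") or None
        out.append(
            MatureAnnotation(row["precursor_id"], row["mature_name"], start, end, canonical)
        )
    return out


def read_mfe_tsv(path: PathLike) -> dict[str, float]:
    """Read per-precursor minimum free energies (kcal/mol)."""
    out: dict[str, float] = {}
    for lineno, row in _tsv_rows(path, ["precursor_id", "mfe"]):
        try:
            out[row["precursor_id"]] = float(row["mfe"])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric mfe {row['mfe']!r}") from None
    return out


def read_read_stack_tsv(path: PathLike) -> list[ReadStack]:
    """Read aligned reads and group them into per-precursor stacks.

    Duplicate (precursor_id, read_seq, start) rows are merged by summing
    counts — the same pooling the upstream multiple alignments apply across
    experiments.  Stack order follows first appearance in the file.
    """
    stacks: dict[str, dict[tuple[str, int], int]] = {}
    for lineno, row in _tsv_rows(
        path, ["precursor_id", "read_seq", "start", "count"]
    ):
        start = _parse_int(row["start"], "start", path, lineno)
        count = _parse_int(row["count"], "count", path, lineno)
        if count <= 0:
            raise ValidationError(f"{path}:{lineno}: count {count} must be >= 1")
        seq = normalize_rna(row["read_seq"])
        key = (seq, start)
        per = stacks.setdefault(row["precursor_id"], {})
        per[key] = per.get(key, 0) + count
    return [
        ReadStack(pid, [AlignedRead(seq, start, c) for (seq, start), c in per.items()])
        for pid, per in stacks.items()
    ]


def read_annotation_sets(path: PathLike) -> dict[str, set[str]]:
    """Read term -> precursor-id sets (term name TAB comma-separated ids)."""
    sets: dict[str, set[str]] = {}
    for lineno, row in _tsv_rows(path, ["term_name", "precursor_ids"]):
        term = row["term_name"]
        if term in sets:
            raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
        members = {p.strip() for p in row["precursor_ids"].split(",") if p.strip()}
        if not members:
            raise ValidationError(f"{path}:{lineno}: term {term!r} has no members")
        sets[term] = members
    return sets


def write_annotation_sets(sets: dict[str, set[str]], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_name\tprecursor_ids\n")
        for term, members in sets.items():
            fh.write(f"{term}\t{','.join(sorted(members))}\n")


# ---------------------------------------------------------------------------
# miRBase-style alignment blocks
# ---------------------------------------------------------------------------

def parse_mirbase_alignment(text: str, precursor_id: str = "aln") -> ReadStack:
    """Best-effort parser for a miRBase-style deep-sequencing alignment block.

    The block holds a precursor line followed by read lines padded with a
    filler character (``-`` or ``.``) outside the read span; each read line
    ends with a whitespace-delimited count token.  A read's start is the
    index of its first non-filler character; reads may run past the
    precursor 3' end (non-templated tailing).

    An optional leading ``>`` header names the precursor.
    """
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty alignment block")
    if lines[0].lstrip().startswith(">"):
        precursor_id = lines[0].lstrip()[1:].split()[0]
        lines = lines[1:]
    if not lines:
        raise FormatError("alignment block has a header but no sequences")

    precursor_line = lines[0].split()[0]
    precursor_len = len(precursor_line)

    reads: dict[tuple[str, int], int] = {}
    for ln in lines[1:]:
        tokens = ln.split()
        if len(tokens) < 2:
            raise FormatError(f"read line missing count token: {ln!r}")
        padded = tokens[0]
        try:
            count = int(tokens[-1])
        except ValueError:
            raise FormatError(f"read line count token not an integer: {ln!r}") from None
        stripped = padded.strip(_FILLERS)
        if not stripped:
            raise FormatError(f"read line holds no bases: {ln!r}")
        if any(ch in _FILLERS for ch in stripped):
            raise FormatError(f"read line has internal gaps (reads are gapless): {ln!r}")
        start = len(padded) - len(padded.lstrip(_FILLERS))
        if start >= precursor_len:
            raise FormatError(
                f"read starts at {start}, beyond the {precursor_len}-nt precursor: {ln!r}"
            )
        seq = normalize_rna(stripped)
        overhang = start + len(seq) - precursor_len
        if overhang > 0:
            logger.debug(
                "read at %d overhangs the precursor 3' end by %d nt", start, overhang
            )
        key = (seq, start)
        reads[key] = reads.get(key, 0) + count

    return ReadStack(
        precursor_id, [AlignedRead(seq, start, c) for (seq, start), c in reads.items()]
    )


def render_mirbase_alignment(stack: ReadStack, precursor: PrecursorRecord) -> str:
    """Render a stack back into the miRBase-style block (inverse of the parser)."""
    width = max([len(precursor)] + [r.end for r in stack.reads])
    lines = [f">{precursor.precursor_id}", precursor.sequence.ljust(width, "-")]
    for r in stack.reads:
        if r.start < 0:
            raise ValidationError("cannot render a read with a negative start")
        padded = "-" * r.start + r.sequence
        lines.append(f"{padded.ljust(width, '-')} {r.count}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_ENTROPY_COLUMNS = [
    "mature_name",
    "precursor_id",
    "arm",
    "total_count",
    "MIH",
    "MIH5",
    "MIH3",
    "L",
    "L5",
    "L3",
    "precursor_length",
    "mfe",
]


def write_entropy_table(results: list[EntropyResult], path: PathLike) -> None:
    """Write per-mature entropy summaries as TSV (row order = input order)."""
    if not results:
        raise ValidationError("refusing to write an empty entropy table")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ENTROPY_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.mature_name,
                    r.precursor_id,
                    r.arm,
                    r.total_count,
                    f"{r.mih:.6f}",
                    f"{r.mih5:.6f}",
                    f"{r.mih3:.6f}",
                    r.L,
                    r.L5,
                    r.L3,
                    r.precursor_length,
                    "" if r.mfe is None else f"{r.mfe:.4f}",
                ]
            )


def read_entropy_table(path: PathLike) -> list[EntropyResult]:
    """Re-parse a table written by :func:`write_entropy_table`."""
    out = []
    for lineno, row in _tsv_rows(path, _ENTROPY_COLUMNS[:10]):
        out.append(
            EntropyResult(
                mature_name=row["mature_name"],
                precursor_id=row["precursor_id"],
                arm=row["arm"],
                mih=float(row["MIH"]),
                mih5=float(row["MIH5"]),
                mih3=float(row["MIH3"]),
                total_count=_parse_int(row["total_count"], "total_count", path, lineno),
                L=_parse_int(row["L"], "L", path, lineno),
                L5=_parse_int(row["L5"], "L5", path, lineno),
                L3=_parse_int(row["L3"], "L3", path, lineno),
                precursor_length=_parse_int(
                    row.get("precursor_length", "0"), "precursor_length", path, lineno
                ),
                mfe=float(row["mfe"]) if row.get("mfe") else None,
            )
        )
    return out
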