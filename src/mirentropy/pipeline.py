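"""Pipeline orchestration: compute -> filter -> stats / enrichment.

These functions are the library-level counterparts of the CLI subcommands,
so scripted analyses can run the whole chain without shelling out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import stats as st
from .cohort import (
    MAX_COUNT_DEFAULT,
    MIN_COUNT_DEFAULT,
    assign_reads_to_mature,
    pair_arms,
)
from .entropy_core import compute_mih
from .errors import ConfigurationError, DegenerateDataError, EmptyCohortError, ValidationError
from .types import EntropyResult, MatureAnnotation, PrecursorRecord, ReadStack

logger = logging.getLogger(__name__)


@dataclass
class ComputeSummary:
    results: list[EntropyResult]
    n_matures: int
    n_no_stack: int
    n_filtered_out: int


def compute_cohort(
    precursors: Sequence[PrecursorRecord],
    matures: Sequence[MatureAnnotation],
    stacks: Sequence[ReadStack],
    mfe: Optional[dict[str, float]] = None,
    min_count: int = MIN_COUNT_DEFAULT,
    max_count: int = MAX_COUNT_DEFAULT,
) -> ComputeSummary:
    """Entropy results for every mature whose isomiR substack passes the filter.

    Each mature's stack is the subset of its precursor's reads whose ends
    fall within +-4 nt of the canonical ends; the strict depth filter
    applies to that per-mature count, so two matures sharing a precursor
    are retained or rejected independently.
    """
    if min_count >= max_count:
        raise ConfigurationError(
            f"min count {min_count} must be below max count {max_count}"
        )
    by_id = {p.precursor_id: p for p in precursors}
    stacks_by_id = {s.precursor_id: s for s in stacks}
    results: list[EntropyResult] = []
    n_no_stack = n_filtered = 0
    for mature in matures:
        precursor = by_id.get(mature.precursor_id)
        if precursor is None:
            raise ValidationError(
                f"mature {mature.mature_name!r} references unknown precursor "
                f"{mature.precursor_id!r}"
            )
        if mfe and precursor.mfe is None and mature.precursor_id in mfe:
            precursor = PrecursorRecord(
                precursor.precursor_id, precursor.sequence, mfe[mature.precursor_id]
            )
        stack = stacks_by_id.get(mature.precursor_id)
        if stack is None:
            logger.info("%s: no reads aligned to its precursor", mature.mature_name)
            n_no_stack += 1
            continue
        substack = assign_reads_to_mature(stack, mature)
        depth = substack.total_count
        if not (min_count < depth < max_count):
            logger.info(
                "%s filtered out: %d reads outside (%d, %d)",
                mature.mature_name,
                depth,
                min_count,
                max_count,
            )
            n_filtered += 1
            continue
        results.append(compute_mih(substack, mature, precursor))
    return ComputeSummary(results, len(matures), n_no_stack, n_filtered)


@dataclass
class StatsRow:
    comparison: str
    statistic_name: str
    statistic: Optional[float]
    p_value: Optional[float]
    n: int
    status: str  # "ok" | "skipped: <reason>"


def _skipped(comparison: str, stat_name: str, reason: str, n: int = 0) -> StatsRow:
    return StatsRow(comparison, stat_name, None, None, n, f"skipped: {reason}")


def _pearson_row(name: str, x, y) -> StatsRow:
    x, y = np.asarray(x, float), np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        return _skipped(name, "pearson_r", "fewer than 3 pairs", len(x))
    try:
        res = st.pearson(x, y)
    except DegenerateDataError as exc:
        return _skipped(name, "pearson_r", str(exc), len(x))
    return StatsRow(name, "pearson_r", res.r, res.p_value, res.n, "ok")


def run_stats(results: Sequence[EntropyResult]) -> list[StatsRow]:
    """The full comparison battery over a computed cohort.

    One row per comparison: the arm-class KS test on MIH, the paired
    signed-rank tests on the end entropies, and the eight correlation
    panels (entropy vs precursor length / MFE / depth, and between arms).
    Comparisons that cannot run are emitted as skipped rows, never dropped.
    """
    results = list(results)
    rows: list[StatsRow] = []

    both_arms = [r.mih for r in results if r.arm in ("5p", "3p")]
    single = [r.mih for r in results if r.arm == "single"]
    if both_arms and single:
        ks = st.ks_two_sample(both_arms, single)
        rows.append(
            StatsRow("ks_mih_arms_vs_single", "ks_d", ks.d_stat, ks.p_value, ks.n1 + ks.n2, "ok")
        )
    else:
        rows.append(
            _skipped("ks_mih_arms_vs_single", "ks_d", "need both arm-class and single-arm results")
        )

    pairs = pair_arms(results)
    for key in ("mih5", "mih3"):
        name = f"wilcoxon_{key}_5p_vs_3p"
        if len(pairs) < 1:
            rows.append(_skipped(name, "wilcoxon_w", "no complete 5p/3p pairs"))
            continue
        a = [getattr(p.result_5p, key) for p in pairs]
        b = [getattr(p.result_3p, key) for p in pairs]
        try:
            res = st.wilcoxon_signed_rank(a, b)
        except DegenerateDataError as exc:
            rows.append(_skipped(name, "wilcoxon_w", str(exc), len(pairs)))
            continue
        rows.append(StatsRow(name, "wilcoxon_w", res.w_stat, res.p_value, res.n_effective, "ok"))

    lengths = [r.precursor_length for r in results]
    mfes = [r.mfe if r.mfe is not None else np.nan for r in results]
    counts = [r.total_count for r in results]
    rows.append(_pearson_row("pearson_mih_vs_length", [r.mih for r in results], lengths))
    rows.append(_pearson_row("pearson_mih_vs_mfe", [r.mih for r in results], mfes))
    rows.append(_pearson_row("pearson_mih5_vs_length", [r.mih5 for r in results], lengths))
    rows.append(_pearson_row("pearson_mih5_vs_mfe", [r.mih5 for r in results], mfes))
    rows.append(_pearson_row("pearson_mih3_vs_length", [r.mih3 for r in results], lengths))
    rows.append(_pearson_row("pearson_mih3_vs_mfe", [r.mih3 for r in results], mfes))
    rows.append(_pearson_row("pearson_mih_vs_count", [r.mih for r in results], counts))
    rows.append(
        _pearson_row(
            "pearson_high_vs_low_mih",
            [p.high_mih for p in pairs],
            [p.low_mih for p in pairs],
        )
    )
    return rows


def run_enrichment(
    results: Sequence[EntropyResult],
    sets: dict[str, set[str]],
    key: str = "mih5",
    fraction: float = st.TOP_FRACTION_DEFAULT,
    alpha: float = 0.05,
) -> list[st.EnrichmentRow]:
    """Top-fraction selection, redundancy removal and hypergeometric enrichment.

    The reference universe is every precursor present in the computed
    cohort (all precursors with characterized isomiRs).
    """
    if not sets:
        raise ValidationError("annotation sets are empty")
    selected_results = st.top_fraction(list(results), key=key, fraction=fraction)
    selected = st.collapse_to_precursors(selected_results)
    reference = {r.precursor_id for r in results}
    return st.enrich(selected, reference, sets, alpha=alpha)


def require_nonempty(summary: ComputeSummary) -> ComputeSummary:
    if not summary.results:
        raise EmptyCohortError(
            f"no mature miRNA survived the depth filter "
            f"({summary.n_filtered_out} filtered, {summary.n_no_stack} without reads)"
        )
    return summary
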