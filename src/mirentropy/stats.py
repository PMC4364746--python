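"""Statistical battery for entropy cohorts.

Two-sample Kolmogorov-Smirnov (arm classes vs single-arm products), paired
Wilcoxon signed-rank (5'- and 3'-end heterogeneity between the two arms of
a precursor), Pearson correlation (entropy vs precursor length, folding
energy, depth, and between arms), top-fraction selection feeding a
one-sided hypergeometric set-enrichment with Benjamini-Hochberg FDR.

The signed-rank test is implemented here rather than delegated: small
cohorts need an exact two-sided p under midranked ties, which the usual
library routines refuse to combine.  Enumeration runs through the exact
distribution of W+ (a subset-sum convolution over doubled midranks) up to
25 effective pairs; beyond that a tie-corrected normal approximation with
continuity correction takes over.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateDataError, ValidationError
from .types import EntropyResult

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25
TOP_FRACTION_DEFAULT = 0.15


@dataclass(frozen=True)
class KSResult:
    d_stat: float
    p_value: float
    n1: int
    n2: int


@dataclass(frozen=True)
class WilcoxonResult:
    w_stat: float
    p_value: float
    n_effective: int
    exact: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    overlap_count: int
    term_size: int
    p_value: float
    fdr: float
    significant: bool


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def ks_two_sample(x, y) -> KSResult:
    """Two-sided two-sample KS test.

    The statistic is the supremum over all observed points of the absolute
    ECDF difference; the p-value comes from the asymptotic Kolmogorov
    distribution at effective sample size ``n1*n2/(n1+n2)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("KS test needs at least one value in each sample")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n1
    cdf_y = np.searchsorted(y, grid, side="right") / n2
    d = float(np.abs(cdf_x - cdf_y).max())
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(special.kolmogorov(math.sqrt(en) * d), 0.0, 1.0))
    return KSResult(d, p, n1, n2)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_decompose(a, b):
    """Drop zero differences and midrank the absolute differences.

    Returns (signs, ranks) with ranks possibly half-integral under ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-d arrays")
    if len(a) == 0:
        raise ValidationError("paired samples are empty")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))  # midranks under ties
    return np.sign(d), ranks


def _exact_wplus_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Exact counts of sign patterns per value of 2*W+ (subset-sum DP).

    ``ranks2`` are the doubled midranks (integers).  Entry t of the result
    counts the sign assignments with 2*W+ == t; the array sums to 2^n.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(a, b) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; ties take midranks.  The reported
    statistic is ``min(W+, W-)``.  Up to 25 effective pairs the two-sided p
    is exact (full enumeration of the sign-pattern distribution, doubling
    the smaller tail and capping at 1); above that a normal approximation
    with continuity correction and tie-corrected variance is used.
    """
    signs, ranks = _signed_rank_decompose(a, b)
    n = len(ranks)
    w_plus = float(ranks[signs > 0].sum())
    w_minus = float(ranks[signs < 0].sum())
    w_stat = min(w_plus, w_minus)

    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.round(ranks * 2).astype(int)
        dist = _exact_wplus_distribution(ranks2)
        total_patterns = dist.sum()
        t_obs = int(round(w_plus * 2))
        p_le = dist[: t_obs + 1].sum() / total_patterns
        p_ge = dist[t_obs:].sum() / total_patterns
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_stat, float(p), n, exact=True)

    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        raise DegenerateDataError("zero variance in signed-rank statistic")
    cc = 0.5 * np.sign(w_plus - mu)  # continuity correction toward the mean
    z = (w_plus - cc - mu) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_stat, p, n, exact=False)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("correlation samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError(f"correlation needs at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in a correlation input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n)


# ---------------------------------------------------------------------------
# selection and enrichment
# ---------------------------------------------------------------------------

_KEYS = {"mih": "mih", "mih5": "mih5", "mih3": "mih3"}


def top_fraction(
    results: list[EntropyResult],
    key: str = "mih",
    fraction: float = TOP_FRACTION_DEFAULT,
) -> list[EntropyResult]:
    """Select the top ``ceil(fraction * n)`` results by an entropy key.

    Every result tied with the cutoff value is included, so the selection
    may exceed the nominal count under ties.
    """
    attr = _KEYS.get(key.lower())
    if attr is None:
        raise ConfigurationError(f"unknown entropy key {key!r}; use mih, mih5 or mih3")
    if not results:
        raise ValidationError("no results to select from")
    if not (0 < fraction <= 1):
        raise ConfigurationError(f"fraction {fraction} outside (0, 1]")
    values = [getattr(r, attr) for r in results]
    k = math.ceil(fraction * len(results))
    cutoff = sorted(values, reverse=True)[k - 1]
    return [r for r in results if getattr(r, attr) >= cutoff]


def collapse_to_precursors(selected: list[EntropyResult]) -> set[str]:
    """Unique precursor ids of the selected matures (redundancy removal)."""
    return {r.precursor_id for r in selected}


def enrich(
    selected: set[str],
    reference: set[str],
    sets: dict[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment of the selected precursors.

    Each term set is intersected with the reference universe before
    testing; empty intersections are skipped.  P-values are upper-tail
    hypergeometric probabilities of the observed overlap; BH FDR runs
    across all tested terms; rows come back sorted by p ascending and are
    flagged significant at ``p < alpha``.
    """
    if not selected <= reference:
        extra = sorted(selected - reference)[:5]
        raise ValidationError(
            f"selected set is not contained in the reference set (e.g. {extra})"
        )
    M, N = len(reference), len(selected)
    tested: list[tuple[str, int, int, float]] = []
    for term, members in sets.items():
        in_ref = members & reference
        if not in_ref:
            logger.info("term %r skipped: no members in the reference set", term)
            continue
        k = len(members & selected)
        p = float(sps.hypergeom.sf(k - 1, M, len(in_ref), N))
        tested.append((term, k, len(in_ref), min(p, 1.0)))
    if not tested:
        return []
    pvals = [t[3] for t in tested]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        EnrichmentRow(term, k, size, p, float(f), p < alpha)
        for (term, k, size, p), f in zip(tested, fdrs)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows
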