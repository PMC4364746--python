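"""Statistical battery against independent enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from mirentropy import (
    ConfigurationError,
    DegenerateDataError,
    ValidationError,
    collapse_to_precursors,
    enrich,
    ks_two_sample,
    pearson,
    top_fraction,
    wilcoxon_signed_rank,
)
from test_cohort import result_of


# ---------------------------------------------------------------------------
# oracles (independent of the implementations they check)
# ---------------------------------------------------------------------------

def ks_oracle(x, y):
    """Sup of |ECDF_x - ECDF_y| by direct counting at every observed point."""
    points = sorted(set(x) | set(y))
    best = 0.0
    for t in points:
        fx = sum(v <= t for v in x) / len(x)
        fy = sum(v <= t for v in y) / len(y)
        best = max(best, abs(fx - fy))
    return best


def wilcoxon_oracle(a, b):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = [ai - bi for ai, bi in zip(a, b) if ai != bi]
    n = len(d)
    absd = [abs(v) for v in d]
    # midranks
    order = sorted(range(n), key=lambda i: absd[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and absd[order[j]] == absd[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    w_plus = sum(r for r, v in zip(ranks, d) if v > 0)
    w_all = []
    for signs in itertools.product((1, -1), repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s > 0))
    p_le = sum(w <= w_plus + 1e-9 for w in w_all) / len(w_all)
    p_ge = sum(w >= w_plus - 1e-9 for w in w_all) / len(w_all)
    return min(1.0, 2.0 * min(p_le, p_ge))


def hypergeom_oracle(n_ref, term, n_sel, k_obs):
    """P(overlap >= k) by enumerating every size-n_sel draw from the urn."""
    universe = range(n_ref)
    term_set = set(range(term))
    hits = total = 0
    for draw in itertools.combinations(universe, n_sel):
        total += 1
        if len(term_set & set(draw)) >= k_obs:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# KS
# ---------------------------------------------------------------------------

class TestKS:
    def test_identical_multisets(self):
        res = ks_two_sample([1, 2, 2, 3], [2, 1, 3, 2])
        assert res.d_stat == 0.0

    def test_disjoint_supports(self):
        assert ks_two_sample([0], [1]).d_stat == 1.0

    def test_interleaved(self):
        assert ks_two_sample([1, 3], [2, 4]).d_stat == pytest.approx(0.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [1.0])

    def test_statistic_matches_scipy_and_p_matches_kolmogorov_series(self, rng):
        from scipy.stats import ks_2samp

        for _ in range(10):
            x = rng.normal(size=30)
            y = rng.normal(0.5, 1.2, size=40)
            res = ks_two_sample(x, y)
            ref = ks_2samp(x, y, method="asymp")
            assert res.d_stat == pytest.approx(ref.statistic, abs=1e-12)
            # classical limiting series Q(z) = 2 sum (-1)^{k-1} exp(-2 k^2 z^2)
            z = math.sqrt(len(x) * len(y) / (len(x) + len(y))) * res.d_stat
            q = 2.0 * sum((-1) ** (k - 1) * math.exp(-2 * k * k * z * z)
                          for k in range(1, 101))
            assert res.p_value == pytest.approx(q, abs=1e-9)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        x=hst.lists(hst.integers(0, 5), min_size=1, max_size=6),
        y=hst.lists(hst.integers(0, 5), min_size=1, max_size=6),
    )
    def test_symmetry_and_monotone_invariance(self, x, y):
        res = ks_two_sample(x, y)
        assert res.d_stat == pytest.approx(ks_two_sample(y, x).d_stat)
        fx = [math.exp(v) for v in x]
        fy = [math.exp(v) for v in y]
        assert ks_two_sample(fx, fy).d_stat == pytest.approx(res.d_stat)
        assert res.d_stat == pytest.approx(ks_oracle(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.w_stat == 0.0
        assert res.p_value == pytest.approx(0.0625)
        assert res.exact

    def test_balanced_antisymmetric(self):
        res = wilcoxon_signed_rank([0, 1], [1, 0])
        assert res.p_value == pytest.approx(1.0)
        assert res.w_stat == pytest.approx(1.5)

    def test_single_pair(self):
        res = wilcoxon_signed_rank([1.0], [0.0])
        assert res.p_value == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([1, 2, 3, 5], [1, 1, 1, 1])
        assert res.n_effective == 3

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1, 2], [1, 2])

    def test_exact_matches_enumeration_with_ties(self, rng):
        for n in range(2, 9):
            for _ in range(30):
                d = rng.integers(-3, 4, size=n)
                a = d.astype(float)
                b = np.zeros(n)
                if np.all(d == 0):
                    continue
                res = wilcoxon_signed_rank(a, b)
                assert res.p_value == pytest.approx(wilcoxon_oracle(a, b), abs=1e-12)

    def test_large_n_tracks_normal_approximation(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        a = rng.normal(0.2, 1.0, size=60)
        b = rng.normal(0.0, 1.0, size=60)
        res = wilcoxon_signed_rank(a, b)
        ref = scipy_wilcoxon(a, b, correction=True, method="approx")
        assert not res.exact
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

class TestPearson:
    def test_affine_increasing(self, rng):
        x = rng.normal(size=20)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_affine_decreasing(self):
        x = [1.0, 2.0, 4.0]
        assert pearson(x, [-v for v in x]).r == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_half(self):
        res = pearson([1, 2, 3], [1, 3, 2])
        assert res.r == pytest.approx(0.5)

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            pearson([1, 2], [3, 4])

    def test_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            pearson([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# selection + enrichment
# ---------------------------------------------------------------------------

class TestTopFraction:
    def make(self, values):
        return [result_of(f"m{i}-5p", f"p{i}", v) for i, v in enumerate(values)]

    def test_ceiling_selection(self, rng):
        results = self.make(rng.permutation(np.linspace(0.01, 0.99, 20)))
        assert len(top_fraction(results, "mih", 0.15)) >= 3

    def test_fraction_one_selects_all(self):
        results = self.make([0.1, 0.2, 0.3])
        assert len(top_fraction(results, "mih", 1.0)) == 3

    def test_hand_ranked_cutoff(self):
        results = self.make([0.5, 0.4, 0.4, 0.1])
        sel = top_fraction(results, "mih", 0.25)
        assert [r.mih for r in sel] == [0.5]

    def test_ties_at_cutoff_included(self):
        results = self.make([0.5, 0.5, 0.4, 0.1])
        assert len(top_fraction(results, "mih", 0.25)) == 2

    def test_unknown_key(self):
        with pytest.raises(ConfigurationError):
            top_fraction(self.make([0.1]), "entropy", 0.5)

    def test_collapse_to_precursors(self):
        results = [result_of("m-5p", "p1", 0.5), result_of("m-3p", "p1", 0.4),
                   result_of("x-5p", "p2", 0.3)]
        assert collapse_to_precursors(results) == {"p1", "p2"}
        assert collapse_to_precursors([]) == set()


class TestEnrich:
    def test_worked_urn(self):
        reference = {f"p{i}" for i in range(10)}
        term = {f"p{i}" for i in range(4)}
        selected = {f"p{i}" for i in range(5)}  # overlap 4
        (row,) = enrich(selected, reference, {"t": term})
        assert row.overlap_count == 4
        assert row.p_value == pytest.approx(6 / 252, abs=1e-12)

    def test_term_outside_reference_skipped(self):
        rows = enrich({"p1"}, {"p1", "p2"}, {"t": {"q9"}})
        assert rows == []

    def test_selected_equals_reference_gives_p_one(self):
        ref = {"p1", "p2", "p3"}
        rows = enrich(ref, ref, {"t": {"p1", "p2"}})
        assert all(r.p_value == pytest.approx(1.0) for r in rows)

    def test_selected_outside_reference_rejected(self):
        with pytest.raises(ValidationError):
            enrich({"zz"}, {"p1"}, {"t": {"p1"}})

    def test_matches_urn_enumeration(self, rng):
        for _ in range(15):
            M = int(rng.integers(5, 13))
            t = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            reference = {f"p{i}" for i in range(M)}
            term = {f"p{i}" for i in range(t)}
            selected = set(map(str, rng.choice(sorted(reference), N, replace=False)))
            (row,) = enrich(selected, reference, {"t": term})
            expected = hypergeom_oracle(M, t, N, row.overlap_count)
            assert row.p_value == pytest.approx(expected, abs=1e-12)

    def test_bh_fdr_order_invariant(self, rng):
        reference = {f"p{i}" for i in range(30)}
        selected = set(map(str, rng.choice(sorted(reference), 8, replace=False)))
        sets = {
            f"t{j}": set(map(str, rng.choice(sorted(reference), int(rng.integers(2, 12)),
                                             replace=False)))
            for j in range(6)
        }
        rows1 = enrich(selected, reference, sets)
        shuffled = dict(reversed(list(sets.items())))
        rows2 = enrich(selected, reference, shuffled)
        as_map = lambda rows: {r.term: (r.p_value, r.fdr) for r in rows}
        assert as_map(rows1) == as_map(rows2)
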