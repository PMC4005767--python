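"""Incomplete-list Spearman rho, ZIC, and the set-overlap measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from pairstab import (
    PairEntry,
    RankedPairList,
    extend_ranks,
    jaccard_topk,
    overlap_fractions,
    rho_curve,
    spearman_incomplete,
    zic,
)
from pairstab.ranking import _prefix_rho_stream, default_grid


def _lists_from_universe(rng, universe, k):
    return list(rng.choice(universe, size=k, replace=False))


class TestExtendRanks:
    def test_identical_lists_keep_ranks(self):
        ra, rb, union = extend_ranks(list("abc"), list("abc"))
        assert ra.tolist() == [1, 2, 3] and rb.tolist() == [1, 2, 3]
        assert union == list("abc")

    def test_disjoint_midrank(self):
        # absent elements of a 2-list in a 4-union share (2+1+4)/2 = 3.5
        ra, rb, union = extend_ranks(["x", "y"], ["u", "w"])
        assert ra.tolist() == [1, 2, 3.5, 3.5]
        assert rb.tolist() == [3.5, 3.5, 1, 2]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_extended_mean_rank_preserved(self, seed):
        """The extension keeps the fractional-ranking mean (m+1)/2."""
        rng = np.random.default_rng(seed)
        universe = np.arange(50)
        a = _lists_from_universe(rng, universe, int(rng.integers(1, 20)))
        b = _lists_from_universe(rng, universe, int(rng.integers(1, 20)))
        ra, rb, union = extend_ranks(a, b)
        m = len(union)
        assert ra.mean() == pytest.approx((m + 1) / 2)
        assert rb.mean() == pytest.approx((m + 1) / 2)


class TestSpearmanIncomplete:
    def test_identical_lists(self):
        assert spearman_incomplete(list("abcdef"), list("abcdef")) == pytest.approx(1.0)

    def test_disjoint_two_element_lists(self):
        # direct evaluation of the 4-element extension
        assert spearman_incomplete(["x", "y"], ["u", "w"]) == pytest.approx(-8 / 9)

    def test_reduces_to_classical_on_shared_elements(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            items = [f"e{i}" for i in range(n)]
            a = list(rng.permutation(items))
            b = list(rng.permutation(items))
            ra = {x: r for r, x in enumerate(a, 1)}
            rb = {x: r for r, x in enumerate(b, 1)}
            classical = spearmanr([ra[x] for x in items], [rb[x] for x in items]).statistic
            assert spearman_incomplete(a, b) == pytest.approx(classical, abs=1e-12)

    def test_symmetry(self, rng):
        universe = np.arange(100)
        for _ in range(20):
            a = _lists_from_universe(rng, universe, 15)
            b = _lists_from_universe(rng, universe, 10)
            assert spearman_incomplete(a, b) == pytest.approx(spearman_incomplete(b, a))

    def test_both_empty_is_an_error(self):
        with pytest.raises(ValueError):
            spearman_incomplete([], [])

    def test_negative_under_independent_selection(self, rng):
        # the rationale for a zero crossing: unrelated top-k draws from a
        # large universe anticorrelate under the extension
        universe = np.arange(10_000)
        rhos = [
            spearman_incomplete(
                _lists_from_universe(rng, universe, 20),
                _lists_from_universe(rng, universe, 20),
            )
            for _ in range(1000)
        ]
        assert np.mean(rhos) < 0

    def test_accepts_ranked_pair_lists(self):
        entries = [PairEntry(0, 1, "a", "b", 2.0, 0.1), PairEntry(0, 2, "a", "c", 1.0, 0.2)]
        rl = RankedPairList(entries, k_requested=5)
        assert spearman_incomplete(rl, rl) == pytest.approx(1.0)


class TestPrefixStreamConsistency:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_incremental_matches_explicit(self, seed):
        """The O(k) closed-form prefix stream equals the explicit extension."""
        rng = np.random.default_rng(seed)
        universe = np.arange(60)
        a = _lists_from_universe(rng, universe, 25)
        b = _lists_from_universe(rng, universe, 25)
        for k, rho in _prefix_rho_stream(a, b, 25):
            explicit = spearman_incomplete(a[:k], b[:k])
            if rho is None:
                assert explicit == 0.0
            else:
                assert rho == pytest.approx(explicit, abs=1e-10)


class TestRhoCurve:
    def test_identical_lists_constant_one(self):
        items = [f"p{i}" for i in range(300)]
        curve = rho_curve(items, items)
        # k = 1 is the degenerate constant-rank point (0 by convention)
        assert curve.rhos[0] == 0.0 and curve.ks[0] == 1
        assert np.allclose(curve.rhos[1:], 1.0)

    def test_shared_prefix_perfect_at_prefix_end(self, rng):
        shared = [f"s{i}" for i in range(100)]
        a = shared + [f"a{i}" for i in range(100)]
        b = shared + [f"b{i}" for i in range(100)]
        curve = rho_curve(a, b, grid=[50, 100, 150])
        at = dict(zip(curve.ks.tolist(), curve.rhos.tolist()))
        assert at[100] == pytest.approx(1.0)

    def test_values_bounded(self, rng):
        universe = np.arange(500)
        a = _lists_from_universe(rng, universe, 200)
        b = _lists_from_universe(rng, universe, 200)
        curve = rho_curve(a, b)
        assert (curve.rhos >= -1 - 1e-12).all() and (curve.rhos <= 1 + 1e-12).all()

    def test_default_grid_shape(self):
        grid = default_grid(1000)
        assert grid[0] == 1 and grid[-1] == 1000
        assert (np.diff(grid) > 0).all()
        assert len(grid) < 300  # dense to 200, then geometric


class TestZic:
    def test_identical_lists_censored(self):
        items = [f"p{i}" for i in range(200)]
        z = zic(items, items, tau=10)
        assert z.censored and z.zic == 200

    def test_disjoint_lists_cross_at_tau(self):
        a = [f"a{i}" for i in range(200)]
        b = [f"b{i}" for i in range(200)]
        z = zic(a, b, tau=7)
        assert not z.censored and z.zic == 7

    def test_shared_prefix_crossing_beyond_prefix(self):
        # lists agreeing on their first 500 elements stay correlated there
        shared = [f"s{i}" for i in range(500)]
        a = shared + [f"a{i}" for i in range(300)]
        b = shared + [f"b{i}" for i in range(300)]
        z = zic(a, b, tau=10)
        assert z.zic > 500

    def test_crossing_found_on_exact_sequence(self, rng):
        # the crossing is searched per-k, not on the display grid
        universe = np.arange(4000)
        a = _lists_from_universe(rng, universe, 300)
        b = _lists_from_universe(rng, universe, 300)
        z = zic(a, b, tau=5)
        rhos = dict(_prefix_rho_stream(a, b, 300))
        if not z.censored:
            assert rhos[z.zic] <= 0
            for k in range(5, z.zic):
                assert rhos[k] is None or rhos[k] > 0

    def test_tau_validation(self):
        with pytest.raises(ValueError):
            zic(["a"], ["a"], tau=0)


class TestSetOverlap:
    def test_jaccard_examples(self):
        a = list("abcd") + list("wxyz")
        b = list("abef") + list("stuv")
        assert jaccard_topk(a, a, 4) == 1.0
        assert jaccard_topk(list("abcd"), list("efgh"), 4) == 0.0
        assert jaccard_topk(a, b, 4) == pytest.approx(1 / 3)  # 2 shared, union 6

    def test_overlap_fraction_examples(self):
        a = list("abcd")
        b = list("abef")
        assert overlap_fractions(a, a, 4) == (0.0, 1.0, 0.0)
        assert overlap_fractions(list("abcd"), list("efgh"), 4) == (0.5, 0.0, 0.5)
        assert overlap_fractions(a, b, 4) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_fractions_sum_to_one_and_match_jaccard(self, rng):
        universe = np.arange(200)
        for _ in range(50):
            a = _lists_from_universe(rng, universe, 30)
            b = _lists_from_universe(rng, universe, 30)
            only_a, both, only_b = overlap_fractions(a, b, 30)
            assert only_a + both + only_b == pytest.approx(1.0)
            assert both == pytest.approx(jaccard_topk(a, b, 30))
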