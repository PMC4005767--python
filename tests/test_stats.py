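"""The three pair-association statistics and their building blocks."""

import numpy as np
import pytest

from pairstab import (
    boost_lrt,
    chi2_test,
    fit_main_effects,
    gss_test,
    hull_union,
    ksa_screen,
    prevalence_map,
    roc_from_table,
)
from pairstab.stats import RocCurve, chi2_logsf, gss_log_p_from_counts


def _random_cube(rng, lam=8, positive=True):
    cube = rng.poisson(lam, (3, 3, 2)).astype(float)
    if positive:
        cube += 1
    return cube


class TestChi2:
    def test_hand_derived_statistic(self):
        # all six expected counts are 20, so X^2 = sum (O-20)^2/20 = 20
        r = chi2_test(np.array([[10, 20, 30], [30, 20, 10]]))
        assert r.statistic == pytest.approx(20.0)
        assert r.df == 2
        # closed form for df=2: Q(1, x/2) = exp(-x/2)
        assert r.p_value == pytest.approx(np.exp(-10.0), rel=1e-12)

    def test_identical_rows_give_zero(self):
        r = chi2_test(np.array([[7, 3, 5], [7, 3, 5]]))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_bivariate_df_is_eight(self, rng):
        table = rng.poisson(5, (2, 9)) + 1
        assert chi2_test(table).df == 8

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi2_test(np.array([[1, 2, 3], [0, 0, 0]]))

    def test_zero_expected_cells_contribute_nothing(self):
        # empty genotype column: df stays V-1 but the column adds 0
        full = chi2_test(np.array([[10, 20, 0], [30, 20, 0]]))
        assert full.df == 2
        assert np.isfinite(full.statistic)

    def test_log_space_survives_huge_samples(self):
        # a million samples with strong association: p underflows but log p is finite
        assert np.isfinite(chi2_logsf(2e6, 8))
        assert chi2_logsf(2e6, 8) < -1e5

    def test_monotone_in_statistic(self):
        xs = [1.0, 10.0, 100.0, 1000.0]
        logs = [chi2_logsf(x, 8) for x in xs]
        assert all(a > b for a, b in zip(logs, logs[1:]))


class TestLoglinear:
    def test_fitted_margins_match_observed(self, rng):
        # the defining property of IPF on [X1X2][X1Y][X2Y]
        for _ in range(50):
            cube = _random_cube(rng)
            fit = fit_main_effects(cube)
            assert fit.converged
            assert np.abs(fit.fitted.sum(axis=2) - cube.sum(axis=2)).max() < 1e-6
            assert np.abs(fit.fitted.sum(axis=1) - cube.sum(axis=1)).max() < 1e-6
            assert np.abs(fit.fitted.sum(axis=0) - cube.sum(axis=0)).max() < 1e-6

    def test_model_satisfying_table_reproduced(self, rng):
        # no three-way structure: mu(g1,g2,y) = a(g1,g2) b(g1,y) c(g2,y) is a fixed point
        a = rng.uniform(0.5, 2, (3, 3))
        b = rng.uniform(0.5, 2, (3, 2))
        c = rng.uniform(0.5, 2, (3, 2))
        cube = a[:, :, None] * b[:, None, :] * c[None, :, :]
        fit = fit_main_effects(cube)
        assert np.abs(fit.fitted - cube).max() < 1e-6

    def test_uniform_table_is_fixed_point(self):
        cube = np.full((3, 3, 2), 4.0)
        fit = fit_main_effects(cube)
        assert np.abs(fit.fitted - cube).max() < 1e-9

    def test_lrt_zero_without_interaction(self, rng):
        a = rng.uniform(0.5, 2, (3, 3))
        b = rng.uniform(0.5, 2, (3, 2))
        c = rng.uniform(0.5, 2, (3, 2))
        cube = 50 * a[:, :, None] * b[:, None, :] * c[None, :, :]
        r = boost_lrt(cube)
        assert r.statistic == pytest.approx(0.0, abs=1e-6)
        assert r.df == 4

    def test_lrt_nonnegative_and_consistent(self, rng):
        for _ in range(50):
            cube = _random_cube(rng)
            r = boost_lrt(cube)
            assert r.statistic >= 0.0
            fit = fit_main_effects(cube)
            pos = cube > 0
            direct = 2 * (cube[pos] * np.log(cube[pos] / fit.fitted[pos])).sum()
            assert r.statistic == pytest.approx(max(direct, 0.0), abs=1e-9)

    def test_pair_table_input_accepted(self, rng):
        table = rng.poisson(6, (2, 9)) + 1
        assert boost_lrt(table).df == 4


class TestKsaScreen:
    def test_independent_margins_give_zero(self):
        p1 = np.array([0.2, 0.5, 0.3])
        p2 = np.array([0.6, 0.3, 0.1])
        py = np.array([0.5, 0.5])
        cube = 1000 * p1[:, None, None] * p2[None, :, None] * py[None, None, :]
        assert ksa_screen(cube) == pytest.approx(0.0, abs=1e-9)

    def test_upper_bounds_the_lrt(self, rng):
        # the screening property: the Kirkwood value can only over-state the LRT
        for _ in range(500):
            cube = _random_cube(rng, lam=6)
            assert ksa_screen(cube) >= boost_lrt(cube).statistic - 1e-8


class TestRoc:
    def test_prevalence_definition(self):
        t = np.array([[1, 4, 0], [3, 0, 0]])
        phi = prevalence_map(t)
        assert phi[0] == pytest.approx(0.75)  # 3 cases / 4 carriers
        assert phi[1] == 0.0  # all controls
        assert phi[2] == 0.0  # empty cell

    def test_toy_curve_vertices(self):
        roc = roc_from_table(np.array([[4, 2, 0], [0, 2, 4]]))
        expect = [[0, 0], [0, 2 / 3], [1 / 3, 1], [1, 1]]
        assert np.allclose(roc.points, expect)
        assert roc.cum_counts.tolist() == [[0, 0], [0, 4], [2, 6], [6, 6]]

    def test_single_genotype_is_two_endpoints(self):
        roc = roc_from_table(np.array([[5, 0, 0], [3, 0, 0]]))
        assert np.allclose(roc.points, [[0, 0], [1, 1]])

    def test_perfect_separator_passes_corner(self):
        roc = roc_from_table(np.array([[0, 5, 5], [8, 0, 0]]))
        assert any(np.allclose(pt, [0, 1]) for pt in roc.points)


class TestHull:
    @staticmethod
    def _curve(points, n0=10, n1=10):
        pts = np.asarray(points, dtype=float)
        cum = np.column_stack([np.rint(pts[:, 0] * n0), np.rint(pts[:, 1] * n1)]).astype(int)
        return RocCurve(points=pts, cum_counts=cum, n_cases=n1, n_controls=n0)

    def test_idempotent(self):
        r = self._curve([[0, 0], [0.2, 0.6], [0.5, 0.8], [1, 1]])
        h = hull_union(r, r)
        hh = hull_union(h, h)
        assert np.allclose(h.points, hh.points)

    def test_dominates_both_inputs(self):
        r1 = self._curve([[0, 0], [0.2, 0.4], [1, 1]])
        r2 = self._curve([[0, 0], [0.5, 0.9], [1, 1]])
        h = hull_union(r1, r2)
        hx, hy = h.points[:, 0], h.points[:, 1]
        ux = np.unique(hx)
        uy = np.array([hy[hx == v].max() for v in ux])
        for pts in (r1.points, r2.points):
            for x, y in pts:
                assert np.interp(x, ux, uy) >= y - 1e-12

    def test_hull_matches_brute_force(self):
        # brute-force check: (0.2,0.4) lies above the chord (0,0)-(0.5,0.9)
        # (chord height 0.36), so the concave chain keeps both interior points
        r1 = self._curve([[0, 0], [0.2, 0.4], [1, 1]])
        r2 = self._curve([[0, 0], [0.5, 0.9], [1, 1]])
        h = hull_union(r1, r2)
        assert np.allclose(h.points, [[0, 0], [0.2, 0.4], [0.5, 0.9], [1, 1]])
        # and a point below the chord is dropped
        r3 = self._curve([[0, 0], [0.3, 0.3], [1, 1]])
        h2 = hull_union(r3, r2)
        assert np.allclose(h2.points, [[0, 0], [0.5, 0.9], [1, 1]])

    def test_mismatched_totals_rejected(self):
        r1 = self._curve([[0, 0], [1, 1]], n0=10, n1=10)
        r2 = self._curve([[0, 0], [1, 1]], n0=9, n1=10)
        with pytest.raises(ValueError):
            hull_union(r1, r2)


class TestGss:
    def test_constant_second_snp_has_no_gain(self):
        # pair ROC identical to SNP1's ROC: every vertex sits on the null hull
        tab = np.zeros((2, 9), dtype=int)
        tab[0, [0, 3, 6]] = [4, 2, 0]
        tab[1, [0, 3, 6]] = [0, 2, 4]
        assert gss_test(tab).p_value == 1.0

    def test_xor_table_is_highly_significant(self):
        xor = np.array([[10, 1, 10, 1, 10, 1, 10, 1, 10], [1, 10, 1, 10, 1, 10, 1, 10, 1]])
        r = gss_test(xor)
        assert r.p_value < 1e-6
        assert r.statistic == pytest.approx(-np.log10(r.p_value), rel=1e-9)

    def test_p_in_unit_interval_on_random_tables(self, rng):
        for _ in range(300):
            tab = rng.poisson(3, (2, 9))
            if tab[0].sum() == 0 or tab[1].sum() == 0:
                continue
            p = gss_test(tab).p_value
            assert 0.0 < p <= 1.0

    def test_replacing_snp_with_constant_never_helps(self, rng):
        # collapsing SNP2 onto one genotype cannot decrease the p-value
        for _ in range(50):
            tab = rng.poisson(4, (2, 9)) + 1
            p_pair = gss_test(tab).p_value
            collapsed = np.zeros_like(tab)
            collapsed[:, [0, 3, 6]] = tab.reshape(2, 3, 3).sum(axis=2)
            assert gss_test(collapsed).p_value >= p_pair - 1e-12

    def test_log_space_survives_huge_samples(self):
        xor = 10**5 * np.array(
            [[10, 1, 10, 1, 10, 1, 10, 1, 10], [1, 10, 1, 10, 1, 10, 1, 10, 1]]
        )
        log_p = gss_log_p_from_counts(xor)
        assert np.isfinite(log_p) and log_p < -1e4

    def test_degenerate_table_gives_p_one(self):
        tab = np.zeros((2, 9), dtype=int)
        tab[1, 4] = 5
        assert gss_test(tab).p_value == 1.0
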