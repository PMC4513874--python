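"""Spline fitting, derivative inner products, RMS scaling and fPCA."""

import numpy as np
import pandas as pd
import pytest

from mirdyn.fda import (Curve, cosine_similarity, evaluate, fit_curves,
                        fpca, gram_matrix, inner_product, make_basis,
                        rms_scale)
from conftest import MICROARRAY_GRID, toy_fc


class TestBasis:
    @pytest.mark.parametrize("n_points,order,expected", [
        (17, 4, 19),   # microarray schedule, cubic
        (4, 4, 6),     # minimal cubic basis
        (5, 2, 5),     # piecewise linear
    ])
    def test_basis_count_is_interior_knots_plus_order(self, n_points, order,
                                                      expected):
        grid = np.linspace(1, 10, n_points)
        basis = make_basis(grid, order=order)
        assert basis.n_basis == expected
        # the count is real: the design matrix has that many columns
        assert basis.basis_matrix(grid).shape == (n_points, expected)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            make_basis([1.0, 2.0, 3.0], order=4)

    def test_partition_of_unity(self):
        basis = make_basis(MICROARRAY_GRID)
        x = np.linspace(2, 112, 301)
        assert np.allclose(basis.basis_matrix(x).sum(axis=1), 1.0)


class TestFit:
    def test_linear_data_reproduced_for_any_lambda(self):
        t = np.array(MICROARRAY_GRID)
        for lam in (0.05, 10.0, 1e4):
            cs = fit_curves(toy_fc(0.3 * t - 1.0), make_basis(t, lam=lam))
            assert np.abs(cs.evaluate(t) - (0.3 * t - 1.0)).max() < 1e-8

    def test_zero_lambda_interpolates(self):
        t = np.array(MICROARRAY_GRID)
        y = np.random.default_rng(0).normal(size=(3, 17))
        cs = fit_curves(toy_fc(y), make_basis(t, lam=0.0))
        assert np.abs(cs.evaluate(t) - y).max() < 1e-8

    def test_huge_lambda_approaches_ols_line(self):
        t = np.array(MICROARRAY_GRID)
        y = np.random.default_rng(1).normal(size=17)
        cs = fit_curves(toy_fc(y), make_basis(t, lam=1e9))
        slope, icpt = np.polyfit(t, y, 1)
        assert np.abs(cs.evaluate(t)[0] - (slope * t + icpt)).max() < 1e-3

    def test_missing_values_rejected(self):
        fc = toy_fc(np.ones(17))
        fc.iloc[0, 3] = np.nan
        with pytest.raises(ValueError, match="impute"):
            fit_curves(fc, make_basis(MICROARRAY_GRID))


class TestEvaluate:
    def test_first_derivative_of_line_is_one_everywhere(self):
        t = np.linspace(0, 10, 15)
        cs = fit_curves(toy_fc(t, times=t), make_basis(t, lam=0.05))
        dense = np.linspace(0, 10, 100)
        assert np.abs(cs.evaluate(dense, deriv_order=1) - 1.0).max() < 1e-5

    def test_second_derivative_of_parabola_on_dense_grid(self):
        t = np.linspace(0, 10, 41)
        cs = fit_curves(toy_fc(t ** 2, times=t), make_basis(t, lam=1e-6))
        interior = np.linspace(2, 8, 50)
        assert np.abs(cs.evaluate(interior, deriv_order=2) - 2.0).max() \
            < 1e-2

    def test_zero_order_evaluation_reproduces_fit_at_knots(self):
        t = np.array(MICROARRAY_GRID)
        y = np.sin(t / 15)
        cs = fit_curves(toy_fc(y), make_basis(t, lam=0.0))
        assert np.abs(cs.evaluate(t, deriv_order=0) - y).max() < 1e-8

    def test_out_of_range_time_raises(self):
        basis = make_basis(MICROARRAY_GRID)
        cs = fit_curves(toy_fc(np.ones(17)), basis)
        with pytest.raises(ValueError, match="outside"):
            cs.evaluate([150.0])


class TestInnerProduct:
    def test_analytic_integral_of_derivatives(self):
        # f = t^2, g = t on [0,1]: int 2t * 1 dt = 1.  Cubics lie in the
        # order-4 spline space, so represent them exactly via projection.
        t = np.linspace(0, 1, 12)
        basis = make_basis(t)
        dense = np.linspace(0, 1, 200)
        B = basis.basis_matrix(dense)
        f = Curve(np.linalg.lstsq(B, dense ** 2, rcond=None)[0], basis)
        g = Curve(np.linalg.lstsq(B, dense, rcond=None)[0], basis)
        assert inner_product(f, g, deriv_order=1, window=(0, 1)) == \
            pytest.approx(1.0, abs=1e-6)

    def test_gram_inner_product_matches_dense_quadrature(self):
        rng = np.random.default_rng(7)
        basis = make_basis(MICROARRAY_GRID)
        c1 = Curve(rng.normal(size=basis.n_basis), basis)
        c2 = Curve(rng.normal(size=basis.n_basis), basis)
        for d, window in [(0, None), (1, (2, 20)), (1, (22, 112))]:
            lo, hi = (basis.t_min, basis.t_max) if window is None else window
            x = np.linspace(lo, hi, 100001)
            oracle = np.trapezoid(evaluate(c1, x, d) * evaluate(c2, x, d), x)
            got = inner_product(c1, c2, deriv_order=d, window=window)
            assert got == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_self_inner_product_nonnegative(self):
        rng = np.random.default_rng(3)
        basis = make_basis(MICROARRAY_GRID)
        for _ in range(10):
            c = Curve(rng.normal(size=basis.n_basis), basis)
            assert inner_product(c, c, deriv_order=1) >= 0

    def test_mismatched_bases_rejected(self):
        b1 = make_basis(MICROARRAY_GRID)
        b2 = make_basis(np.linspace(0, 10, 17))
        with pytest.raises(ValueError, match="share"):
            inner_product(Curve(np.zeros(b1.n_basis), b1),
                          Curve(np.zeros(b2.n_basis), b2))


class TestRmsScale:
    def test_constant_curve_scales_to_unit_magnitude(self):
        # window-RMS of a constant c is |c|; scaling preserves sign
        for c, expected in ((2.5, 1.0), (-2.5, -1.0)):
            cs = fit_curves(toy_fc(np.full(17, c)),
                            make_basis(MICROARRAY_GRID))
            scaled = rms_scale(cs)
            assert np.allclose(
                scaled.evaluate(np.array(MICROARRAY_GRID)), expected,
                atol=1e-6)

    def test_scale_invariance(self):
        y = np.sin(np.array(MICROARRAY_GRID) / 10)
        cs1 = rms_scale(fit_curves(toy_fc(y), make_basis(MICROARRAY_GRID)))
        cs2 = rms_scale(fit_curves(toy_fc(2 * y),
                                   make_basis(MICROARRAY_GRID)))
        assert np.allclose(cs1.coefficients, cs2.coefficients)

    def test_unit_rms_by_quadrature(self, default_curves):
        window = (2.0, 20.0)
        scaled = rms_scale(default_curves, window=window)
        x = np.linspace(*window, 4001)
        vals = scaled.subset(scaled.gene_ids[:20]).evaluate(x)
        rms = np.sqrt(np.trapezoid(vals ** 2, x) / (window[1] - window[0]))
        assert np.allclose(rms, 1.0, atol=1e-6)

    def test_zero_curve_excluded_with_warning(self):
        y = np.vstack([np.zeros(17), np.ones(17)])
        cs = fit_curves(toy_fc(y), make_basis(MICROARRAY_GRID))
        with pytest.warns(UserWarning, match="zero-RMS"):
            scaled = rms_scale(cs)
        assert scaled.gene_ids == ["g1"]


class TestFpca:
    def test_identical_curves_report_zero_variance(self):
        cs = fit_curves(toy_fc(np.tile(np.ones(17), (4, 1))),
                        make_basis(MICROARRAY_GRID))
        with pytest.warns(UserWarning, match="zero total variance"):
            res = fpca(cs, 1)
        assert res.harmonics.shape[0] == 0

    def test_planted_one_component_model(self):
        t = np.linspace(0, 10, 12)
        h = np.exp(-0.5 * ((t - 5) / 1.5) ** 2)
        a = np.random.default_rng(0).normal(size=30)
        cs = fit_curves(toy_fc(0.3 + np.outer(a, h), times=t),
                        make_basis(t, lam=0.0))
        with pytest.warns(UserWarning, match="truncating"):
            res = fpca(cs, 2)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-8)
        # first harmonic proportional to the planted bump
        dense = np.linspace(0, 10, 400)
        h1 = res.harmonic(0)(dense)
        hd = np.exp(-0.5 * ((dense - 5) / 1.5) ** 2)
        hd_c = hd - np.trapezoid(hd, dense) / 10
        corr = np.corrcoef(h1, hd_c)[0, 1]
        assert abs(corr) > 0.99

    def test_harmonics_l2_orthonormal(self, default_curves):
        res = fpca(default_curves, 3)
        G = gram_matrix(default_curves.basis, 0)
        gram = res.harmonics @ G @ res.harmonics.T
        assert np.abs(gram - np.eye(3)).max() < 1e-6

    def test_variance_fractions_sorted_and_sum_to_one_at_full_rank(self):
        t = np.linspace(0, 5, 8)
        y = np.random.default_rng(5).normal(size=(6, 8))
        cs = fit_curves(toy_fc(y, times=t), make_basis(t))
        res = fpca(cs, 5)  # rank = n-1 = 5
        vf = res.variance_fractions
        assert np.all(np.diff(vf) <= 1e-12) and np.all(vf >= 0)
        assert vf.sum() == pytest.approx(1.0, abs=1e-8)

    def test_coefficient_fpca_matches_discretized_oracle(self):
        t = np.linspace(0, 10, 12)
        y = np.random.default_rng(11).normal(size=(25, 12))
        cs = fit_curves(toy_fc(y, times=t), make_basis(t))
        res = fpca(cs, 3)
        # oracle: weighted PCA of finely discretized curves
        grid = np.linspace(0, 10, 3001)
        w = np.gradient(grid)
        V = cs.evaluate(grid)
        V = V - V.mean(axis=0)
        C = (V * w).T @ V / (len(y) - 1)
        ev = np.linalg.eigvalsh(C)[::-1]
        oracle_vf = ev[:3] / ev[ev > 0].sum()
        assert np.allclose(res.variance_fractions, oracle_vf, atol=1e-4)

    def test_first_harmonic_excursion_peaks_at_planted_times(self):
        from mirdyn.synthetic import SynthConfig, generate_timecourse
        from scipy.signal import argrelmax
        cfg = SynthConfig(rng_seed=1, n_indirect=0, n_nontarget=0,
                          n_housekeeping=0, amplitude_jitter_sd=0.5,
                          noise_sd=0.05)
        ds = generate_timecourse(cfg)
        res = fpca(fit_curves(ds.fc, make_basis(cfg.time_grid)), 1)
        tg = np.array(cfg.time_grid)
        exc = np.abs(res.excursion(0)(tg) - res.mean(tg))
        peaks = argrelmax(exc)[0]
        top2 = sorted(peaks, key=lambda i: -exc[i])[:2]
        times = sorted(tg[top2])
        # within one grid step of the planted 4 h and 32 h peaks
        assert 2 <= times[0] <= 6
        assert 26 <= times[1] <= 40


class TestCosineSimilarity:
    def test_self_similarity_one(self, scaled_early):
        sub = scaled_early.subset(scaled_early.gene_ids[:15])
        S = cosine_similarity(sub, window=(2, 20))
        assert np.allclose(np.diag(S), 1.0, atol=1e-8)
        assert np.abs(S).max() <= 1.0 + 1e-12
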