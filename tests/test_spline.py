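"""Restricted cubic spline, inflection location, BCa bootstrap."""

from __future__ import annotations

import numpy as np
import pytest

from hbref.spline import (
    BootstrapFailureError,
    InsufficientCurvatureError,
    RcsFit,
    bca_ci,
    find_inflections,
    fit_rcs,
    predict,
    rcs_basis,
    run_hb_stfr_analysis,
    second_derivative,
)
from hbref.synthetic import child_config, generate_stfr, make_two_phase_curve

KNOTS = (2.0, 4.0, 6.0, 9.0, 14.0)


def _textbook_basis(x, t):
    """Independent natural-spline construction (scalar loops, no reuse)."""
    def pos3(v):
        return max(v, 0.0) ** 3

    out = []
    for xi in x:
        row = [1.0, xi]
        for j in range(3):
            cj = (pos3(xi - t[j])
                  - pos3(xi - t[3]) * (t[4] - t[j]) / (t[4] - t[3])
                  + pos3(xi - t[4]) * (t[3] - t[j]) / (t[4] - t[3]))
            row.append(cj)
        out.append(row)
    return np.array(out)


class TestFitRcs:
    def test_linear_data_recovers_slope_with_null_curvature(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1.0, 16.0, 500)
        y = 14.0 - 0.3 * x
        fit = fit_rcs(x, y, knots=KNOTS)
        assert fit.coeffs[1] == pytest.approx(-0.3, abs=1e-8)
        assert np.allclose(fit.coeffs[2:], 0.0, atol=1e-8)
        with pytest.raises(InsufficientCurvatureError):
            find_inflections(fit)

    def test_basis_matches_independent_textbook_construction(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.5, 16.0, 10)
        assert np.allclose(rcs_basis(x, KNOTS), _textbook_basis(x, KNOTS),
                           rtol=1e-12, atol=1e-12)

    def test_fitted_values_at_probe_points_match_textbook_fit(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1.0, 15.0, 800)
        y = 12.0 - 0.2 * x + 0.01 * (x - 6.0) ** 2 + rng.normal(0, 0.3, 800)
        fit = fit_rcs(x, y, knots=KNOTS)
        probes = np.linspace(2.5, 13.0, 10)
        coef, *_ = np.linalg.lstsq(_textbook_basis(x, KNOTS), y, rcond=None)
        expect = _textbook_basis(probes, KNOTS) @ coef
        assert np.allclose(predict(fit, probes), expect, atol=1e-7)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1.0, 15.0, 300)
        y = 12.0 - 0.2 * x + rng.normal(0, 0.2, 300)
        perm = rng.permutation(300)
        a = fit_rcs(x, y, knots=KNOTS)
        b = fit_rcs(x[perm], y[perm], knots=KNOTS)
        assert np.allclose(a.coeffs, b.coeffs, atol=1e-9)

    def test_degenerate_spread_raises_knot_collision(self):
        x = np.full(100, 5.0)
        with pytest.raises(ValueError, match="knot"):
            fit_rcs(x, np.ones(100))


class TestSecondDerivative:
    @pytest.fixture()
    def fit(self):
        return RcsFit(knots=KNOTS, coeffs=(12.0, -0.2, 0.05, -0.1, 0.08), n=0)

    def test_exactly_zero_outside_boundary_knots(self, fit):
        assert second_derivative(fit, 1.5) == 0.0
        assert second_derivative(fit, 14.0) == 0.0
        assert second_derivative(fit, 20.0) == 0.0

    def test_matches_central_finite_differences(self, fit):
        # probes keep clear of knots, where the FD stencil straddles the
        # third-derivative jump; error is relative to the curvature scale
        h = 1e-4
        xs = np.linspace(KNOTS[0] + 0.05, KNOTS[4] - 0.05, 100)
        xs = xs[np.min(np.abs(xs[:, None] - np.array(KNOTS)[None, :]), axis=1) > 0.02]
        assert len(xs) >= 95

        # extended-precision FD oracle: the cubic basis cancels ~1e-13 in
        # float64, which /h^2 would amplify above the tolerance
        def f_ld(v):
            t = np.array(KNOTS, dtype=np.longdouble)
            v = v.astype(np.longdouble)
            c = np.array(fit.coeffs, dtype=np.longdouble)
            pos3 = lambda u: np.maximum(u, 0) ** 3
            out = c[0] + c[1] * v
            for j in range(3):
                out += c[2 + j] * (
                    pos3(v - t[j])
                    - pos3(v - t[3]) * (t[4] - t[j]) / (t[4] - t[3])
                    + pos3(v - t[4]) * (t[3] - t[j]) / (t[4] - t[3])
                )
            return out

        fd = ((f_ld(xs + h) - 2 * f_ld(xs) + f_ld(xs - h)) / h**2).astype(float)
        ana = second_derivative(fit, xs)
        assert np.max(np.abs(ana - fd)) / np.max(np.abs(fd)) < 1e-5

    def test_integral_consistent_with_first_derivative_difference(self, fit):
        # piecewise integral of f'' equals the change in f' (internal check)
        h = 1e-6
        xs = np.linspace(KNOTS[0], KNOTS[4], 200001)
        integral = np.trapezoid(second_derivative(fit, xs), xs)
        fprime = lambda v: (
            (predict(fit, [v + h]) - predict(fit, [v - h])) / (2 * h)
        ).item()
        # f' is continuous at the boundary knots; evaluate just inside
        assert integral == pytest.approx(
            fprime(KNOTS[4] - 1e-4) - fprime(KNOTS[0] + 1e-4), abs=1e-4
        )


class TestFindInflections:
    def test_construct_then_recover_roots_closed_form(self):
        curve = make_two_phase_curve(KNOTS, (-0.15, 0.20, -0.08), -0.2, 9.6)
        fit = curve.as_fit()
        roots = [r for r, _ in find_inflections(fit)]
        # independent root computation: solve each linear segment of f''
        t = np.array(KNOTS)
        g = np.array([second_derivative(fit, float(v)) for v in t])
        expect = []
        for s in range(4):
            if g[s] * g[s + 1] < 0:
                expect.append(t[s] + g[s] / (g[s] - g[s + 1]) * (t[s + 1] - t[s]))
        assert len(roots) == 2
        assert np.allclose(roots, expect, atol=1e-8)
        # exact zero of the analytic second derivative at each root
        for r in roots:
            assert abs(second_derivative(fit, r)) < 1e-10

    def test_ordering_first_then_second(self):
        curve = child_config(seed=0).stfr_curve
        (x1, h1), (x2, h2) = find_inflections(curve.as_fit())
        assert x1 < x2
        assert h1 > h2  # Hb declines with rising sTfR

    def test_scale_equivariance_in_hb(self):
        rng = np.random.default_rng(4)
        cfg = child_config(seed=5)
        records, _ = generate_stfr(cfg, n=3000)
        x = np.array([r.stfr for r in records])
        y = np.array([r.hb for r in records])
        a = find_inflections(fit_rcs(x, y, knots=cfg.stfr_curve.knots))
        b = find_inflections(fit_rcs(x, 2.0 * y, knots=cfg.stfr_curve.knots))
        for (xa, ha), (xb, hb_) in zip(a, b):
            assert xb == pytest.approx(xa, abs=1e-9)   # sTfR coords unchanged
            assert hb_ == pytest.approx(2.0 * ha, rel=1e-9)


class TestBca:
    def test_symmetric_mean_bca_close_to_percentile(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.0, 1.0, 400)
        dummy = np.zeros_like(x)
        stat = lambda xs, ys: float(np.mean(xs))
        (lo, hi), details = bca_ci(x, dummy, stat, B=2000, seed=1,
                                   return_details=True)
        assert abs(details["z0"]) < 0.15
        assert abs(details["a"]) < 0.05
        boots = _bootstrap_means(x, 2000, seed=1)
        p_lo, p_hi = np.quantile(boots, [0.025, 0.975])
        se = np.std(boots)
        assert lo == pytest.approx(p_lo, abs=0.5 * se)
        assert hi == pytest.approx(p_hi, abs=0.5 * se)

    def test_constant_statistic_zero_width(self):
        x = np.arange(100.0)
        stat = lambda xs, ys: 42.0
        lo, hi = bca_ci(x, x, stat, B=500, seed=0)
        assert lo == hi == 42.0

    def test_failing_resamples_beyond_budget_abort(self):
        x = np.arange(200.0)
        calls = {"n": 0}

        def stat(xs, ys):
            calls["n"] += 1
            if calls["n"] > 1 and calls["n"] % 2 == 0:
                raise InsufficientCurvatureError("gone")
            return float(np.mean(xs))

        with pytest.raises(BootstrapFailureError):
            bca_ci(x, x, stat, B=500, seed=0)


def _bootstrap_means(x, B, seed):
    rng = np.random.Generator(np.random.Philox(seed))
    out = np.empty(B)
    for b in range(B):
        out[b] = np.mean(x[rng.integers(0, x.size, x.size)])
    return out


class TestEndToEnd:
    def test_records_without_stfr_rejected(self):
        from conftest import make_child

        records = [make_child() for _ in range(100)]
        with pytest.raises(ValueError, match="sTfR"):
            run_hb_stfr_analysis(records, "child", B=500, seed=0)

    def test_seeded_runs_are_bit_identical(self):
        cfg = child_config(seed=8)
        records, _ = generate_stfr(cfg, n=1500)
        a = run_hb_stfr_analysis(records, "child", B=500, seed=3,
                                 knots=cfg.stfr_curve.knots)
        b = run_hb_stfr_analysis(records, "child", B=500, seed=3,
                                 knots=cfg.stfr_curve.knots)
        assert a == b

    def test_noisy_recovery_of_planted_curve_shape(self):
        cfg = child_config(seed=9)
        records, truth = generate_stfr(cfg, n=4000)
        res = run_hb_stfr_analysis(records, "child", B=500, seed=4,
                                   knots=cfg.stfr_curve.knots)
        assert res.first[0] < res.second[0]
        assert res.second[1] == pytest.approx(truth["true_inflection2_hb"],
                                              abs=0.15)
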