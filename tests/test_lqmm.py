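"""Quantile mixed model: likelihood, optimisation, ICC, LR test."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, stats

from hbref.lqmm import (
    QuantileMixedFit,
    SingularDesignError,
    ald_variance_factor,
    fit_lqmm,
    icc_from_fit,
    lr_test_random_intercept,
    marginal_loglik,
)
from hbref.synthetic import child_config, generate_cohort

from conftest import make_child, make_woman

P = 0.05


def _toy_records(seed, k=2, n_per=30, beta0=10.0, sigma=0.3, psi=0.4):
    """Intercept-only ALD data: the exact generative model of the fit."""
    rng = np.random.default_rng(seed)
    records = []
    for j in range(k):
        uj = rng.normal(0.0, psi)
        eps = sigma * (rng.exponential(size=n_per) / P
                       - rng.exponential(size=n_per) / (1.0 - P))
        for v in beta0 + uj + eps:
            records.append(make_child(survey_id=f"S{j:02d}",
                                      hb=float(np.clip(v, 0.5, 20.0))))
    return records


def _arrays(records):
    y = np.array([r.hb for r in records])
    codes = np.array([r.survey_id for r in records])
    order = np.argsort(codes, kind="mergesort")
    return y[order], codes[order]


# ------------------------------------------------------------------ oracles

def _gh_loglik_oracle(y, codes, p, beta0, sigma, psi, n_nodes=11):
    """Independent re-implementation of the adaptive-GH ALD likelihood.

    Mirrors the documented integration scheme (per-survey Gaussian
    posterior proxy, exact importance reweighting) with scalar loops.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    ll = 0.0
    for sid in np.unique(codes):
        yj = y[codes == sid]
        r = yj - beta0
        n_j = len(yj)
        prec = n_j * p * (1 - p) / sigma**2 + 1.0 / psi**2
        s = np.sqrt(1.0 / prec)
        c = (1.0 / prec) * (n_j * p * (1 - p) / sigma**2) * np.quantile(r, p)
        terms = []
        for t_k, w_k in zip(nodes, weights):
            u = c + np.sqrt(2.0) * s * t_k
            e = (r - u) / sigma
            log_ald = np.sum(np.log(p * (1 - p)) - np.log(sigma)
                             - e * (p - (e < 0)))
            log_prior = (-0.5 * u**2 / psi**2
                         - 0.5 * np.log(2 * np.pi) - np.log(psi))
            log_gauss = (-0.5 * (u - c) ** 2 / s**2
                         - 0.5 * np.log(2 * np.pi) - np.log(s))
            terms.append(np.log(w_k) - 0.5 * np.log(np.pi)
                         + log_ald + log_prior - log_gauss)
        m = np.max(terms)
        ll += m + np.log(np.sum(np.exp(np.array(terms) - m)))
    return float(ll)


def _grid_search_loglik(y, codes, p, n_nodes=11):
    """Brute-force grid search over (beta0, sigma, psi); returns max loglik.

    A full-range coarse grid is followed by local grid refinement around
    each of the top coarse cells (not just the single best), because the
    2-survey likelihood has well-separated near-equal modes.
    """
    q05 = np.quantile(y, p)
    coarse = [
        (b0, s, ps)
        for b0 in np.linspace(q05 - 1.5, q05 + 1.5, 41)
        for s in np.linspace(0.05, 0.8, 21)
        for ps in np.linspace(0.02, 2.6, 41)
    ]
    scored = sorted(
        ((_gh_loglik_oracle(y, codes, p, *c, n_nodes), c) for c in coarse),
        reverse=True,
    )
    steps = np.array([3.0 / 40, 0.75 / 20, 2.58 / 40])
    best_ll, best_par = scored[0]
    for _, cell in scored[:8]:
        par = np.array(cell)
        span = steps.copy()
        for _ in range(5):
            grid = [
                (b0, s, ps)
                for b0 in np.linspace(par[0] - 1.5 * span[0], par[0] + 1.5 * span[0], 9)
                for s in np.linspace(max(par[1] - 1.5 * span[1], 1e-3),
                                     par[1] + 1.5 * span[1], 9)
                for ps in np.linspace(max(par[2] - 1.5 * span[2], 1e-4),
                                      par[2] + 1.5 * span[2], 9)
            ]
            local_best = max(
                ((_gh_loglik_oracle(y, codes, p, *c, n_nodes), c) for c in grid)
            )
            if local_best[0] > best_ll:
                best_ll, best_par = local_best[0], np.array(local_best[1])
            par = np.array(local_best[1])
            span *= 3.0 / 8.0
    return best_ll, best_par


class TestLikelihood:
    def test_marginal_loglik_matches_independent_gh_implementation(self):
        records = _toy_records(0)
        y, codes = _arrays(records)
        X = np.ones((y.size, 1))
        for params in [(10.0, 0.3, 0.4), (9.8, 0.25, 0.2), (10.2, 0.4, 0.6)]:
            mine = marginal_loglik(y, X, codes, P, [params[0]],
                                   params[1], params[2], n_nodes=11)
            oracle = _gh_loglik_oracle(y, codes, P, *params, n_nodes=11)
            assert mine == pytest.approx(oracle, abs=1e-8)

    def test_gh_integration_approaches_exact_quadrature(self):
        # adaptive GH converges on the kinked ALD integrand; the quad
        # reference must be peak-shifted, since the raw integrand scale
        # (~1e-22) sits far below quad's absolute tolerance
        records = _toy_records(0)
        y, codes = _arrays(records)
        beta0, sigma, psi = 10.0, 0.3, 0.4

        def quad_ll():
            total = 0.0
            for sid in np.unique(codes):
                yj = y[codes == sid]

                def logh(u):
                    e = (yj - beta0 - u) / sigma
                    return (np.sum(np.log(P * (1 - P)) - np.log(sigma)
                                   - e * (P - (e < 0)))
                            + stats.norm.logpdf(u, 0.0, psi))

                shift = max(logh(u) for u in np.linspace(-6 * psi, 6 * psi, 2001))
                val, _ = integrate.quad(lambda u: np.exp(logh(u) - shift),
                                        -10 * psi, 10 * psi, limit=400)
                total += np.log(val) + shift
            return total

        exact = quad_ll()
        X = np.ones((y.size, 1))
        err41 = abs(marginal_loglik(y, X, codes, P, [beta0], sigma, psi, 41) - exact)
        err11 = abs(marginal_loglik(y, X, codes, P, [beta0], sigma, psi, 11) - exact)
        assert err41 < 0.01
        assert err41 < err11


class TestFit:
    def test_loglik_matches_brute_force_grid_oracle(self):
        records = _toy_records(1)
        fit = fit_lqmm(records, p=P, covariates=(), n_nodes=11, restarts=5)
        y, codes = _arrays(records)
        grid_ll, grid_par = _grid_search_loglik(y, codes, P, n_nodes=11)
        assert fit.loglik == pytest.approx(grid_ll, abs=1e-3)

    def test_location_equivariance(self):
        records = _toy_records(2, k=4, n_per=60)
        shifted = [make_child(survey_id=r.survey_id, hb=r.hb + 1.5, age=r.age)
                   for r in records]
        a = fit_lqmm(records, p=P, covariates=(), restarts=1)
        b = fit_lqmm(shifted, p=P, covariates=(), restarts=1)
        assert b.beta["intercept"] - a.beta["intercept"] == pytest.approx(1.5, abs=1e-5)
        assert b.psi2 == pytest.approx(a.psi2, abs=1e-6)
        assert b.sigma == pytest.approx(a.sigma, abs=1e-6)
        assert b.icc_between == pytest.approx(a.icc_between, abs=1e-6)

    def test_median_fit_with_symmetric_errors_recovers_mean(self):
        rng = np.random.default_rng(3)
        records = []
        for j in range(6):
            for v in rng.normal(11.0, 1.0, 400):
                records.append(make_child(survey_id=f"S{j}", hb=float(v)))
        fit = fit_lqmm(records, p=0.5, covariates=(), restarts=1)
        assert fit.beta["intercept"] == pytest.approx(11.0, abs=0.1)

    def test_age_slope_recovered_from_planted_gradient(self):
        # conditional-P5 age slope of 0.19 g/dL per year, ALD errors
        errs = []
        for seed in (11, 12, 13):
            cfg = child_config(seed=seed, n_surveys=8, n_per_survey=(250, 250),
                               error_family="ald", tau_between=0.3,
                               frac_unhealthy=0.0, sigma_within=1.0,
                               p_survey_has_altitude=0.0)
            records, truth = generate_cohort(cfg)
            fit = fit_lqmm(records, p=P, restarts=1)
            errs.append(fit.beta["age"] - truth["age_slope_p5"])
        assert abs(np.mean(errs)) < 0.05

    def test_requires_two_surveys_and_min_size(self):
        with pytest.raises(ValueError, match="2 surveys"):
            fit_lqmm(_toy_records(4, k=1), p=P, covariates=())
        with pytest.raises(ValueError, match="30 records"):
            fit_lqmm(_toy_records(5, k=2, n_per=10), p=P, covariates=())

    def test_sex_among_women_is_singular(self):
        records = [make_woman(survey_id=f"S{j}", hb=12.0 + 0.01 * i)
                   for j in range(2) for i in range(40)]
        with pytest.raises(SingularDesignError):
            fit_lqmm(records, p=P, covariates=("age", "sex"))


class TestIcc:
    def _fit(self, psi2, sigma, p=P):
        se2 = sigma**2 * ald_variance_factor(p)
        b = psi2 / (psi2 + se2)
        return QuantileMixedFit(
            p=p, beta={"intercept": 10.0}, psi2=psi2, sigma=sigma,
            icc_between=b, icc_within=1 - b, loglik=0.0, converged=True,
            n=100, k_surveys=5, age_center=30.0,
        )

    def test_zero_psi_gives_zero_between(self):
        assert icc_from_fit(self._fit(0.0, 0.3)) == (0.0, 1.0)

    def test_psi_equal_to_residual_variance_gives_half(self):
        sigma = 0.2
        se2 = sigma**2 * ald_variance_factor(P)
        between, within = icc_from_fit(self._fit(se2, sigma))
        assert between == pytest.approx(0.5)
        assert within == pytest.approx(0.5)

    def test_hand_set_values_match_independent_formula(self):
        # independent algebraic form: Var ALD(0,1,p) = 1/p^2 + 1/(1-p)^2
        psi2, sigma = 0.09, 0.1
        between, _ = icc_from_fit(self._fit(psi2, sigma))
        varfac = 1.0 / P**2 + 1.0 / (1.0 - P) ** 2
        assert between == pytest.approx(psi2 / (psi2 + sigma**2 * varfac), abs=1e-12)

    def test_shares_sum_to_one(self):
        between, within = icc_from_fit(self._fit(0.2, 0.15))
        assert between + within == pytest.approx(1.0, abs=1e-12)


class TestLrTest:
    def test_statistic_nonnegative_and_null_not_significant(self):
        cfg = child_config(seed=31, n_surveys=6, n_per_survey=(120, 120),
                           error_family="ald", tau_between=0.0,
                           frac_unhealthy=0.0, p_survey_has_altitude=0.0,
                           age_slope_p5=0.0)  # no omitted-covariate confound
        records, _ = generate_cohort(cfg)
        stat, pval = lr_test_random_intercept(records, p=P, covariates=(),
                                              restarts=1)
        assert stat >= 0.0
        assert pval > 0.005

    def test_strong_survey_effect_detected(self):
        cfg = child_config(seed=32, n_surveys=8, n_per_survey=(150, 150),
                           error_family="ald", tau_between=1.0,
                           frac_unhealthy=0.0, sigma_within=1.0,
                           p_survey_has_altitude=0.0)
        records, _ = generate_cohort(cfg)
        stat, pval = lr_test_random_intercept(records, p=P, covariates=(),
                                              restarts=1)
        assert pval < 1e-3
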