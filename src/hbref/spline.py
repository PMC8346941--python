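"""Hb-for-sTfR restricted cubic spline, inflection points, BCa bootstrap.

Soluble transferrin receptor (sTfR) rises with tissue iron deficiency
and erythropoietic drive, so Hb plotted against sTfR traces the
physiological response to developing anemia: flat at iron sufficiency, a
first downturn where tissue iron deficiency begins, and a second bend
into the steep linear phase of iron-deficient erythropoiesis.  The curve
is modelled as a restricted (natural) cubic spline with 5 knots:

    f(x) = b0 + b1*x + sum_j beta_j * C_j(x),  j = 1..3
    C_j(x) = (x-t_j)+^3 - (x-t4)+^3 (t5-t_j)/(t5-t4)
                        + (x-t5)+^3 (t4-t_j)/(t5-t4)

which is linear beyond the boundary knots, hence f'' == 0 outside
[t1, t5].  f'' is piecewise linear in x, so its sign-change roots — the
inflection points — are found exactly on each inter-knot segment.  The
Hb level at the second inflection is the quantity of interest (onset of
iron-deficient erythropoiesis); its CI comes from a nonparametric pairs
bootstrap with bias-corrected-and-accelerated (BCa) endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .records import IndividualRecord

__all__ = [
    "RcsFit",
    "InflectionResult",
    "InsufficientCurvatureError",
    "BootstrapFailureError",
    "KNOT_QUANTILES_5",
    "rcs_basis",
    "fit_rcs",
    "predict",
    "first_derivative",
    "second_derivative",
    "curve_dump",
    "find_inflections",
    "bca_ci",
    "run_hb_stfr_analysis",
]

#: default quantiles for 5-knot placement (Harrell's convention)
KNOT_QUANTILES_5 = (0.05, 0.275, 0.50, 0.725, 0.95)


class InsufficientCurvatureError(RuntimeError):
    """Fewer than two sign changes of f'' between the boundary knots."""


class BootstrapFailureError(RuntimeError):
    """Too many bootstrap resamples failed to produce the statistic."""


@dataclass(frozen=True)
class RcsFit:
    """A fitted 5-knot restricted cubic spline of Hb on sTfR."""

    knots: tuple[float, ...]   # 5 strictly increasing sTfR values, mg/L
    coeffs: tuple[float, ...]  # (b0, b1, beta1, beta2, beta3), g/dL scale
    n: int

    def __post_init__(self) -> None:
        if len(self.knots) != 5:
            raise ValueError("exactly 5 knots required")
        if not all(a < b for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError("knots must be strictly increasing")
        if len(self.coeffs) != 5:
            raise ValueError("5 coefficients required (intercept, linear, 3 basis)")


@dataclass(frozen=True)
class InflectionResult:
    """Coordinates of the first two inflection points with a BCa CI."""

    first: tuple[float, float]    # (sTfR mg/L, Hb g/dL)
    second: tuple[float, float]
    hb_ci_second: tuple[float, float]
    boot_reps: int
    n_failed: int
    seed: int
    n: int

    def __post_init__(self) -> None:
        if not self.first[0] < self.second[0]:
            raise ValueError("first inflection must be at lower sTfR")
        lo, hi = self.hb_ci_second
        if not (lo <= self.second[1] <= hi):
            raise ValueError("CI must bracket the second-inflection Hb")


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Design matrix [1, x, C1(x), C2(x), C3(x)] for 5 given knots."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    X = np.empty((x.size, 5))
    X[:, 0] = 1.0
    X[:, 1] = x
    d54 = t[4] - t[3]

    def _pcube(u: np.ndarray) -> np.ndarray:
        u = np.maximum(u, 0.0)
        return u * u * u  # (u)+^3 without pow

    c4, c5 = _pcube(x - t[3]), _pcube(x - t[4])
    for j in range(3):
        X[:, 2 + j] = (
            _pcube(x - t[j])
            - c4 * ((t[4] - t[j]) / d54)
            + c5 * ((t[3] - t[j]) / d54)
        )
    return X


def fit_rcs(
    stfr: Sequence[float],
    hb: Sequence[float],
    knots: Sequence[float] | None = None,
    knot_quantiles: Sequence[float] = KNOT_QUANTILES_5,
) -> RcsFit:
    """Least-squares restricted cubic spline fit of Hb on sTfR.

    Knots default to the sTfR sample quantiles in ``knot_quantiles``;
    pass explicit ``knots`` to fix them (e.g. for recovery studies).
    """
    x = np.asarray(stfr, dtype=float)
    y = np.asarray(hb, dtype=float)
    if x.size != y.size:
        raise ValueError("stfr and hb must have equal length")
    if x.size < 50:
        raise ValueError("need at least 50 observations to fit 5-knot spline")
    if np.any(x <= 0):
        raise ValueError("sTfR values must be positive")
    if knots is None:
        knots = np.quantile(x, knot_quantiles)
    knots = tuple(float(k) for k in knots)
    if not all(a < b for a, b in zip(knots, knots[1:])):
        raise ValueError(f"degenerate sTfR spread: knot collision {knots}")
    X = rcs_basis(x, knots)
    # column scaling keeps the normal equations well conditioned (the
    # cubic columns are ~span^3 larger than the linear ones); the scaled
    # solve is then exact enough for noiseless-recovery use
    scale = np.maximum(np.abs(X).max(axis=0), 1e-30)
    Xs = X / scale
    G = Xs.T @ Xs
    b = Xs.T @ y
    try:
        coef = np.linalg.solve(G, b) / scale
    except np.linalg.LinAlgError:
        coef = np.linalg.lstsq(X, y, rcond=None)[0]
    return RcsFit(knots=knots, coeffs=tuple(float(c) for c in coef), n=int(x.size))


def predict(fit: RcsFit, x: Sequence[float]) -> np.ndarray:
    """Fitted Hb at sTfR values x."""
    return rcs_basis(np.atleast_1d(np.asarray(x, dtype=float)), fit.knots) @ np.asarray(fit.coeffs)


def first_derivative(fit: RcsFit, x: Sequence[float] | float) -> np.ndarray | float:
    """Analytic f'(x); continuous everywhere, constant outside [t1, t5]."""
    scalar = np.isscalar(x)
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(fit.knots)
    beta = np.asarray(fit.coeffs[2:])
    d54 = t[4] - t[3]
    out = np.full_like(xv, fit.coeffs[1])
    for j in range(3):
        out += beta[j] * 3.0 * (
            np.maximum(xv - t[j], 0.0) ** 2
            - np.maximum(xv - t[3], 0.0) ** 2 * (t[4] - t[j]) / d54
            + np.maximum(xv - t[4], 0.0) ** 2 * (t[3] - t[j]) / d54
        )
    return float(out[0]) if scalar else out


def curve_dump(fit: RcsFit, n_points: int = 200):
    """Probe-grid table of the fitted curve: (sTfR, Hb, f', f'')."""
    import pandas as pd

    xs = np.linspace(fit.knots[0], fit.knots[4], n_points)
    return pd.DataFrame(
        {
            "stfr": xs,
            "hb_fitted": predict(fit, xs),
            "d1": first_derivative(fit, xs),
            "d2": second_derivative(fit, xs),
        }
    )


def second_derivative(fit: RcsFit, x: Sequence[float] | float) -> np.ndarray | float:
    """Analytic f''(x); piecewise linear, exactly 0 outside [t1, t5]."""
    scalar = np.isscalar(x)
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(fit.knots)
    beta = np.asarray(fit.coeffs[2:])
    d54 = t[4] - t[3]
    out = np.zeros_like(xv)
    for j in range(3):
        out += beta[j] * (
            6.0 * np.maximum(xv - t[j], 0.0)
            - 6.0 * np.maximum(xv - t[3], 0.0) * (t[4] - t[j]) / d54
            + 6.0 * np.maximum(xv - t[4], 0.0) * (t[3] - t[j]) / d54
        )
    # exact zero beyond the boundary knots (natural-spline constraint)
    out[(xv <= t[0]) | (xv >= t[4])] = 0.0
    return float(out[0]) if scalar else out


def find_inflections(fit: RcsFit) -> list[tuple[float, float]]:
    """Sign-change roots of f'' strictly inside (t1, t5), with fitted Hb.

    f'' is linear on each inter-knot segment, so each root is closed
    form.  Raises :class:`InsufficientCurvatureError` when fewer than
    two are found.
    """
    t = np.asarray(fit.knots)
    g = second_derivative(fit, t)  # values at the 5 knots; g[0] = g[4] = 0
    # a fit of effectively linear data leaves machine-noise curvature
    # whose sign changes are meaningless; gate on curvature that moves
    # the fitted values by more than float noise over the knot span
    span = t[4] - t[0]
    y_scale = max(1.0, float(np.max(np.abs(predict(fit, t)))))
    if float(np.max(np.abs(g))) * span**2 <= 1e-9 * y_scale:
        raise InsufficientCurvatureError(
            "curvature indistinguishable from numerical noise"
        )
    roots: list[float] = []
    for seg in range(4):
        a, b = t[seg], t[seg + 1]
        ga, gb = g[seg], g[seg + 1]
        if seg > 0 and ga == 0.0:
            # interior knot lying exactly on zero: root if curvature flips
            prev = g[seg - 1]
            if prev != 0.0 and gb != 0.0 and np.sign(prev) != np.sign(gb):
                roots.append(float(a))
        if ga * gb < 0.0:
            roots.append(float(a + ga / (ga - gb) * (b - a)))
    roots = sorted(set(roots))
    if len(roots) < 2:
        raise InsufficientCurvatureError(
            f"found {len(roots)} inflection point(s); need at least 2"
        )
    hb = predict(fit, roots)
    return [(r, float(h)) for r, h in zip(roots, hb)]


def bca_ci(
    stfr: Sequence[float],
    hb: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float],
    B: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    max_fail_frac: float = 0.10,
    return_details: bool = False,
):
    """Bias-corrected-and-accelerated bootstrap CI for a paired statistic.

    Nonparametric pairs (case) resampling at the original sample size.
    The median-bias correction is z0 = Phi^-1(#{theta* < theta_hat}/B);
    the acceleration is the jackknife skewness
    a = sum(d_i^3) / (6 * sum(d_i^2)^{3/2}), d_i = mean(theta_(.)) - theta_(i).
    Resamples where the statistic fails (e.g. an inflection point
    vanishes) are dropped and counted; more than ``max_fail_frac`` of B
    failing aborts with a diagnostic rather than returning a biased
    interval.
    """
    x = np.asarray(stfr, dtype=float)
    y = np.asarray(hb, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("stfr and hb must have equal length")
    if B < 500:
        raise ValueError("B must be >= 500")
    theta_hat = float(statistic(x, y))  # must succeed on the full sample

    rng = np.random.Generator(np.random.Philox(seed))
    thetas = np.empty(B)
    n_ok = 0
    n_fail = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            thetas[n_ok] = statistic(x[idx], y[idx])
            n_ok += 1
        except (InsufficientCurvatureError, ValueError, np.linalg.LinAlgError):
            n_fail += 1
    if n_fail > max_fail_frac * B:
        raise BootstrapFailureError(
            f"{n_fail}/{B} bootstrap resamples failed to produce the statistic"
        )
    thetas = thetas[:n_ok]

    if np.ptp(thetas) == 0.0 and thetas[0] == theta_hat:
        if return_details:
            return (theta_hat, theta_hat), {"n_failed": n_fail, "z0": 0.0, "a": 0.0}
        return theta_hat, theta_hat

    # median-bias correction
    prop = np.count_nonzero(thetas < theta_hat) / n_ok
    prop = min(max(prop, 0.5 / n_ok), 1.0 - 0.5 / n_ok)
    z0 = stats.norm.ppf(prop)

    # jackknife acceleration (failing leave-one-out fits are dropped)
    jack = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            jack.append(statistic(x[mask], y[mask]))
        except (InsufficientCurvatureError, ValueError, np.linalg.LinAlgError):
            pass
        mask[i] = True
    jack = np.asarray(jack)
    if jack.size < max(3, (1.0 - max_fail_frac) * n):
        raise BootstrapFailureError(
            f"jackknife failed on {n - jack.size}/{n} leave-one-out samples"
        )
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - level
    z = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - a * (z0 + z)))
    lo, hi = np.quantile(thetas, adj)
    if return_details:
        return (float(lo), float(hi)), {"n_failed": n_fail, "z0": float(z0), "a": a}
    return float(lo), float(hi)


def second_inflection_hb(
    stfr: np.ndarray, hb: np.ndarray, knots: Sequence[float] | None = None
) -> float:
    """Statistic: Hb at the second (higher-sTfR) inflection of the RCS fit."""
    fit = fit_rcs(stfr, hb, knots=knots)
    return find_inflections(fit)[1][1]


def run_hb_stfr_analysis(
    records: Sequence[IndividualRecord],
    group: str,
    B: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    knots: Sequence[float] | None = None,
    stfr_transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> InflectionResult:
    """End-to-end erythropoiesis-curve analysis for one target group.

    Uses *all* records of the group with nonmissing sTfR and Hb — no
    healthy filter, so the full physiological range of sTfR enters the
    curve.  Composes the spline fit, exact inflection location, and a
    BCa bootstrap CI on the second inflection's Hb.  The first
    inflection's sTfR marks the onset of tissue iron deficiency.
    ``stfr_transform`` is a hook for assay harmonisation (applied to the
    raw sTfR values before any fitting).
    """
    pairs = [(r.stfr, r.hb) for r in records
             if r.group == group and r.stfr is not None]
    if not pairs:
        raise ValueError(f"no records with nonmissing sTfR for group {group!r}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if stfr_transform is not None:
        x = np.asarray(stfr_transform(x), dtype=float)

    fit = fit_rcs(x, y, knots=knots)
    infl = find_inflections(fit)
    first, second = infl[0], infl[1]

    stat = lambda xs, ys: second_inflection_hb(xs, ys, knots=knots)
    (lo, hi), details = bca_ci(
        x, y, stat, B=B, seed=seed, level=level, return_details=True
    )
    # a heavily biased resampling distribution can fail to bracket the
    # point estimate; widen rather than report an inconsistent interval
    lo, hi = min(lo, second[1]), max(hi, second[1])
    return InflectionResult(
        first=first, second=second, hb_ci_second=(lo, hi),
        boot_reps=B, n_failed=int(details["n_failed"]), seed=seed, n=int(x.size),
    )
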