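"""Synthetic multi-survey generator with planted, recoverable structure.

The generator emulates the statistical structure the whole analysis
assumes about pooled household nutrition surveys:

* survey random intercepts u_j ~ N(0, tau^2) with *small* between-survey
  variance relative to individual spread at the lower tail;
* an individual Hb model mu + u_j + age gradient + error, with a
  contaminating "unhealthy" mixture component shifted downward whose
  members carry biomarker values violating at least one healthy-cohort
  threshold (low ferritin, elevated CRP/AGP, low vitamin A, or malaria);
* survey-by-survey availability of optional markers (vitamin A, malaria,
  altitude, smoking), with altitude and smoking effects planted through
  the same polynomial/decrement the adjustment stage removes;
* a curvilinear Hb-sTfR relationship defined by an explicit restricted
  cubic spline with exactly two planted inflection points, plus Gaussian
  noise, over a right-skewed (lognormal) sTfR marginal.

Individual errors can be drawn as Gaussian (realistic survey noise) or
asymmetric Laplace at the analysis quantile (the exact generative model
of the quantile mixed model, used for parameter-recovery studies; with
ALD errors the conditional p-quantile of Hb is exactly the linear
predictor).  Every planted parameter, including the analytic fifth
percentile of the healthy component, is reported in a truth table so
recovery tests never hard-code numbers.

Randomness uses the counter-based Philox generator for cross-platform
reproducibility; the seed is part of the configuration and of every
truth table.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .adjust import AdjustmentPolicy
from .lqmm import ald_variance_factor
from .records import IndividualRecord
from .spline import RcsFit, find_inflections, predict

__all__ = [
    "StfrCurve",
    "SynthConfig",
    "make_two_phase_curve",
    "child_config",
    "woman_config",
    "generate_cohort",
    "generate_stfr",
    "analytic_healthy_p5",
]


@dataclass(frozen=True)
class StfrCurve:
    """A true Hb-sTfR curve: an RCS with exactly two inflection points."""

    knots: tuple[float, ...]
    coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        fit = self.as_fit()
        roots = find_inflections(fit)  # raises if < 2
        if len(roots) != 2:
            raise ValueError(
                f"stfr_curve must have exactly 2 inflections, found {len(roots)}"
            )

    def as_fit(self) -> RcsFit:
        return RcsFit(knots=self.knots, coeffs=self.coeffs, n=0)

    def inflections(self) -> list[tuple[float, float]]:
        return find_inflections(self.as_fit())

    def __call__(self, x) -> np.ndarray:
        return predict(self.as_fit(), x)


def make_two_phase_curve(
    knots: Sequence[float],
    curvature_at_inner_knots: Sequence[float],
    start_slope: float,
    anchor_hb: float,
) -> StfrCurve:
    """Construct an RCS curve from target curvature values.

    ``curvature_at_inner_knots`` gives f'' at knots t2, t3, t4 (f'' is 0
    at the boundary knots by construction); a (-, +, -) sign pattern
    yields exactly two inflection points.  The basis coefficients are
    solved from those three linear conditions, the linear coefficient is
    ``start_slope`` (the slope below t1), and the intercept is chosen so
    that the fitted Hb at the *second* inflection equals ``anchor_hb``.
    """
    t = np.asarray(knots, dtype=float)
    curv = np.asarray(curvature_at_inner_knots, dtype=float)
    if t.size != 5 or curv.size != 3:
        raise ValueError("need 5 knots and 3 inner-knot curvature targets")
    # at x <= t4 only the first term of each basis second derivative is live
    M = 6.0 * np.maximum(t[1:4, None] - t[None, :3], 0.0)
    beta = np.linalg.solve(M, curv)
    probe = StfrCurve(knots=tuple(t), coeffs=(0.0, start_slope, *beta))
    x2 = probe.inflections()[1][0]
    b0 = anchor_hb - float(probe(x2)[0])
    return StfrCurve(knots=tuple(t), coeffs=(b0, start_slope, *beta))


@dataclass(frozen=True)
class SynthConfig:
    """Planted parameters for one target group's multi-survey cohort."""

    group: str = "child"
    n_surveys: int = 22
    n_per_survey: tuple[int, int] = (500, 3000)  # uniform range, or (n, n)
    mu_hb: float = 11.5            # g/dL, healthy-component location
    sigma_within: float = 1.1      # g/dL, SD of the individual error
    tau_between: float = 0.4       # g/dL, SD of survey intercepts
    age_slope_p5: float = 0.19     # g/dL per year at the modelled quantile
    age_quad: float = 0.0          # g/dL per year^2
    sex_effect: float = 0.0        # g/dL added for boys (children only)
    frac_unhealthy: float = 0.60
    unhealthy_hb_shift: float = -1.2   # g/dL, negative
    error_family: str = "normal"       # 'normal' | 'ald'
    quantile_p: float = 0.05           # location quantile for ALD errors
    p_survey_measures_vita: float = 0.8
    p_survey_measures_malaria: float = 0.6
    p_survey_has_altitude: float = 0.25
    altitude_range: tuple[float, float] = (1200.0, 3000.0)
    p_survey_has_smoking: float = 0.3  # women only
    frac_smokers: float = 0.15
    stfr_curve: StfrCurve | None = None
    noise_stfr: float = 0.8            # g/dL around the true curve
    stfr_lognorm_mu: float = float(np.log(6.0))
    stfr_lognorm_sigma: float = 0.5
    stfr_max: float = 17.0             # mg/L, truncation of the assay range
    n_stfr: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in {"child", "woman"}:
            raise ValueError("group must be 'child' or 'woman'")
        if self.tau_between < 0:
            raise ValueError("tau_between must be >= 0")
        if not (0.0 <= self.frac_unhealthy < 1.0):
            raise ValueError("frac_unhealthy must be in [0, 1)")
        if self.unhealthy_hb_shift > 0:
            raise ValueError("unhealthy_hb_shift must be <= 0")
        if self.error_family not in {"normal", "ald"}:
            raise ValueError("error_family must be 'normal' or 'ald'")
        if self.n_per_survey[0] > self.n_per_survey[1]:
            raise ValueError("n_per_survey range reversed")


# Curvature magnitudes are sized so the (-, +, -) pattern of f'' remains
# resolvable when analysis knots are re-placed at sample quantiles of a
# right-skewed sTfR marginal.
_CHILD_STFR = dict(knots=(2.5, 4.5, 6.2, 8.0, 13.0),
                   curvature_at_inner_knots=(-0.20, 0.25, -0.12),
                   start_slope=-0.15, anchor_hb=9.6)
_WOMAN_STFR = dict(knots=(1.5, 2.6, 3.8, 5.0, 9.0),
                   curvature_at_inner_knots=(-0.50, 0.55, -0.25),
                   start_slope=-0.20, anchor_hb=11.0)


def child_config(seed: int = 0, **overrides) -> SynthConfig:
    """Preschool-children defaults: anemia-range means, strong age gradient."""
    kw = dict(
        group="child", mu_hb=11.5, sigma_within=1.1, tau_between=0.4,
        age_slope_p5=0.19, frac_unhealthy=0.60, unhealthy_hb_shift=-1.2,
        stfr_curve=make_two_phase_curve(**_CHILD_STFR),
        stfr_lognorm_mu=float(np.log(6.0)), stfr_lognorm_sigma=0.5,
        seed=seed,
    )
    kw.update(overrides)
    return SynthConfig(**kw)


def woman_config(seed: int = 0, **overrides) -> SynthConfig:
    """Nonpregnant-women defaults: flat age profile, lower contamination."""
    kw = dict(
        group="woman", mu_hb=12.5, sigma_within=1.05, tau_between=0.4,
        age_slope_p5=-0.03, frac_unhealthy=0.44, unhealthy_hb_shift=-1.0,
        stfr_curve=make_two_phase_curve(**_WOMAN_STFR),
        stfr_lognorm_mu=float(np.log(3.5)), stfr_lognorm_sigma=0.55,
        stfr_max=11.5,
        seed=seed,
    )
    kw.update(overrides)
    return SynthConfig(**kw)


def _draw_errors(rng, cfg: SynthConfig, n: int) -> np.ndarray:
    """Individual errors with SD = sigma_within.

    ALD errors are located so their ``quantile_p`` quantile is 0, making
    the conditional p-quantile of Hb exactly the linear predictor.
    """
    if cfg.error_family == "normal":
        return rng.normal(0.0, cfg.sigma_within, n)
    p = cfg.quantile_p
    scale = cfg.sigma_within / np.sqrt(ald_variance_factor(p))
    return scale * (rng.exponential(size=n) / p
                    - rng.exponential(size=n) / (1.0 - p))


def _age_bounds(group: str) -> tuple[float, float]:
    return (6.0, 59.0) if group == "child" else (15.0, 49.0)


def _error_cdf(cfg: SynthConfig, z: float) -> float:
    """CDF of the individual error at z (closed form per family)."""
    if cfg.error_family == "normal":
        return float(stats.norm.cdf(z / cfg.sigma_within))
    p = cfg.quantile_p
    s = cfg.sigma_within / np.sqrt(ald_variance_factor(p))
    if z < 0:
        return p * float(np.exp((1.0 - p) * z / s))
    return 1.0 - (1.0 - p) * float(np.exp(-p * z / s))


def analytic_healthy_p5(cfg: SynthConfig, p: float = 0.05) -> float:
    """Fifth percentile of the healthy component, from the planted model.

    Marginalises the survey intercept (Gauss-Hermite), the uniform age
    distribution (Gauss-Legendre) and, for children, the sex indicator,
    then root-finds F(x) = p.  Independent of any generated sample.
    """
    gh_t, gh_w = np.polynomial.hermite.hermgauss(41)
    gl_t, gl_w = np.polynomial.legendre.leggauss(41)
    lo, hi = _age_bounds(cfg.group)
    ages = 0.5 * (hi - lo) * gl_t + 0.5 * (hi + lo)
    agew = gl_w / np.sum(gl_w)
    age_y = ages / 12.0 if cfg.group == "child" else ages
    center = np.mean([lo, hi]) / (12.0 if cfg.group == "child" else 1.0)
    a_c = age_y - center
    mean_struct = cfg.mu_hb + cfg.age_slope_p5 * a_c + cfg.age_quad * a_c**2
    if cfg.group == "child" and cfg.sex_effect != 0.0:
        mean_struct = np.concatenate([mean_struct, mean_struct + cfg.sex_effect])
        agew = np.concatenate([agew, agew]) / 2.0
    u = np.sqrt(2.0) * cfg.tau_between * gh_t
    uw = gh_w / np.sqrt(np.pi)

    def cdf(x: float) -> float:
        total = 0.0
        for ui, wi in zip(u, uw):
            for mi, wa in zip(mean_struct, agew):
                total += wi * wa * _error_cdf(cfg, x - mi - ui)
        return total

    span = 8.0 * (cfg.sigma_within + cfg.tau_between) + 2.0
    return float(optimize.brentq(lambda x: cdf(x) - p,
                                 cfg.mu_hb - span, cfg.mu_hb + span, xtol=1e-10))


def generate_cohort(cfg: SynthConfig) -> tuple[list[IndividualRecord], dict]:
    """Generate one group's multi-survey cohort plus its truth table.

    The truth table holds every planted parameter, the analytic healthy
    fifth percentile, the true between-survey variance fraction
    tau^2 / (tau^2 + sigma_within^2), and the quantile-model intercept
    (the conditional fifth percentile at the age center).
    """
    rng = np.random.Generator(np.random.Philox(cfg.seed))
    policy = AdjustmentPolicy()
    lo_age, hi_age = _age_bounds(cfg.group)
    records: list[IndividualRecord] = []

    crit_f = 12.0 if cfg.group == "child" else 15.0  # healthy-filter defaults
    for j in range(cfg.n_surveys):
        sid = f"S{j + 1:02d}"
        n_j = int(rng.integers(cfg.n_per_survey[0], cfg.n_per_survey[1] + 1))
        u_j = rng.normal(0.0, cfg.tau_between)
        measures_vita = rng.random() < cfg.p_survey_measures_vita
        measures_malaria = rng.random() < cfg.p_survey_measures_malaria
        has_altitude = rng.random() < cfg.p_survey_has_altitude
        has_smoking = (cfg.group == "woman"
                       and rng.random() < cfg.p_survey_has_smoking)
        altitude_j = (float(rng.uniform(*cfg.altitude_range))
                      if has_altitude else None)

        age = rng.uniform(lo_age, hi_age, n_j)
        age_y = age / 12.0 if cfg.group == "child" else age
        center = np.mean([lo_age, hi_age]) / (12.0 if cfg.group == "child" else 1.0)
        a_c = age_y - center
        sex = (np.where(rng.random(n_j) < 0.5, "male", "female")
               if cfg.group == "child" else np.full(n_j, "female"))
        unhealthy = rng.random(n_j) < cfg.frac_unhealthy
        hb = (cfg.mu_hb + u_j
              + cfg.age_slope_p5 * a_c + cfg.age_quad * a_c**2
              + np.where(sex == "male", cfg.sex_effect, 0.0)
              + np.where(unhealthy, cfg.unhealthy_hb_shift, 0.0)
              + _draw_errors(rng, cfg, n_j))

        smoker = np.full(n_j, "unmeasured", dtype=object)
        if has_smoking:
            smoker[:] = "negative"
            smokers = rng.random(n_j) < cfg.frac_smokers
            smoker[smokers] = "positive"
            hb = hb + np.where(smokers, policy.smoking_decrement, 0.0)
        if altitude_j is not None and altitude_j >= policy.altitude_floor:
            hb = hb + policy.altitude_correction(altitude_j)
        hb = np.clip(hb, 0.2, 24.8)

        # biomarkers: healthy pass every threshold; unhealthy violate one
        ferritin = crit_f + rng.lognormal(np.log(20.0), 0.8, n_j)
        vita = 20.1 + rng.lognormal(np.log(10.0), 0.5, n_j)
        crp = 0.5 * rng.beta(1.0, 3.0, n_j)
        agp = 1.0 * rng.beta(1.0, 3.0, n_j)
        malaria = np.full(n_j, "negative" if measures_malaria else "unmeasured",
                          dtype=object)
        causes = ["iron", "inflammation"]
        if measures_vita:
            causes.append("vita")
        if measures_malaria:
            causes.append("malaria")
        pick = rng.integers(0, len(causes), n_j)
        for i in np.flatnonzero(unhealthy):
            cause = causes[pick[i]]
            if cause == "iron":
                ferritin[i] = rng.uniform(1.0, crit_f * 0.98)
            elif cause == "inflammation":
                if rng.random() < 0.5:
                    crp[i] = rng.uniform(0.55, 5.0)
                else:
                    agp[i] = rng.uniform(1.05, 3.0)
            elif cause == "vita":
                vita[i] = rng.uniform(5.0, 19.8)
            else:
                malaria[i] = "positive"

        for i in range(n_j):
            records.append(
                IndividualRecord(
                    survey_id=sid,
                    group=cfg.group,
                    age=float(age[i]),
                    sex=str(sex[i]),
                    hb=float(hb[i]),
                    ferritin=float(ferritin[i]),
                    vita=float(vita[i]) if measures_vita else None,
                    crp=float(crp[i]),
                    agp=float(agp[i]),
                    malaria=str(malaria[i]),
                    altitude=altitude_j,
                    smoker=str(smoker[i]),
                )
            )

    center = np.mean(_age_bounds(cfg.group))
    truth = {
        **_config_scalars(cfg),
        "age_center_years": center / (12.0 if cfg.group == "child" else 1.0),
        "true_p5_healthy": analytic_healthy_p5(cfg),
        "true_var_fraction_p5": cfg.tau_between**2
        / (cfg.tau_between**2 + cfg.sigma_within**2),
        "true_intercept_p5": (
            cfg.mu_hb if cfg.error_family == "ald"
            else cfg.mu_hb + stats.norm.ppf(cfg.quantile_p) * cfg.sigma_within
        ),
        "n_records": len(records),
    }
    return records, truth


def _config_scalars(cfg: SynthConfig) -> dict:
    d = {}
    for k, v in asdict(cfg).items():
        if isinstance(v, (int, float, str, bool)):
            d[k] = v
    if cfg.stfr_curve is not None:
        infl = cfg.stfr_curve.inflections()
        d.update(
            true_inflection1_stfr=infl[0][0], true_inflection1_hb=infl[0][1],
            true_inflection2_stfr=infl[1][0], true_inflection2_hb=infl[1][1],
        )
    return d


def generate_stfr(
    cfg: SynthConfig,
    records: Sequence[IndividualRecord] | None = None,
    n: int | None = None,
) -> tuple[list[IndividualRecord], dict]:
    """Records with sTfR drawn so E[Hb | sTfR] is the planted curve.

    sTfR is lognormal (right-skewed, spanning both planted inflections);
    Hb is the curve value plus N(0, noise_stfr) noise.  When ``records``
    are supplied, their identities (survey, age, sex) are kept and a
    fresh (sTfR, Hb) pair replaces the biomarker-driven Hb — this
    mirrors the study design where the erythropoiesis curve uses all
    participants with sTfR, independent of the healthy filter.
    """
    if cfg.stfr_curve is None:
        raise ValueError("config has no stfr_curve")
    rng = np.random.Generator(np.random.Philox([cfg.seed, 7]))
    if records is not None:
        n = len(records)
    elif n is None:
        n = cfg.n_stfr
    stfr = rng.lognormal(cfg.stfr_lognorm_mu, cfg.stfr_lognorm_sigma, n)
    # truncate to the assay's physiological range by redraw, so the
    # linear tail of the planted curve is never extrapolated into
    # impossible Hb values
    for _ in range(100):
        over = stfr > cfg.stfr_max
        if not np.any(over):
            break
        stfr[over] = rng.lognormal(cfg.stfr_lognorm_mu,
                                   cfg.stfr_lognorm_sigma, int(over.sum()))
    stfr = np.minimum(stfr, cfg.stfr_max)
    hb = np.clip(
        np.asarray(cfg.stfr_curve(stfr)) + rng.normal(0.0, cfg.noise_stfr, n),
        0.2, 24.8,
    )
    lo_age, hi_age = _age_bounds(cfg.group)
    out = []
    for i in range(n):
        if records is not None:
            base = records[i]
            out.append(
                IndividualRecord(
                    survey_id=base.survey_id, group=base.group, age=base.age,
                    sex=base.sex, hb=float(hb[i]), stfr=float(stfr[i]),
                )
            )
        else:
            out.append(
                IndividualRecord(
                    survey_id="S01", group=cfg.group,
                    age=float(lo_age + (hi_age - lo_age) * ((i + 0.5) / n)),
                    sex="female", hb=float(hb[i]), stfr=float(stfr[i]),
                )
            )
    infl = cfg.stfr_curve.inflections()
    truth = {
        "true_inflection1_stfr": infl[0][0], "true_inflection1_hb": infl[0][1],
        "true_inflection2_stfr": infl[1][0], "true_inflection2_hb": infl[1][1],
        "noise_stfr": cfg.noise_stfr, "n": n, "seed": cfg.seed,
        "knots": list(cfg.stfr_curve.knots),
        "coeffs": list(cfg.stfr_curve.coeffs),
    }
    return out, truth
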