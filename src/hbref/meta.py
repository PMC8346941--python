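"""Random-effects meta-analysis of survey quantile estimates (REML).

Model: y_i = mu + u_i + e_i with u_i ~ N(0, tau2) (true between-survey
spread of the fifth percentile) and e_i ~ N(0, v_i), v_i the squared
Woodruff SE of survey i.  tau2 is estimated by restricted maximum
likelihood via Fisher scoring with nonnegativity projection; the pooled
mean is the inverse-variance weighted mean at weights 1/(v_i + tau2)
with a Wald (normal-quantile) CI.  Heterogeneity is additionally
summarised by Cochran's Q under fixed-effect weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .quantiles import QuantileEstimate

__all__ = [
    "MetaResult",
    "reml_tau2",
    "reml_loglik",
    "reml_pool",
    "cochran_q",
    "forest_table",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled quantile with heterogeneity summaries."""

    mu_hat: float    # g/dL, pooled estimate
    se_mu: float     # g/dL
    ci_low: float
    ci_high: float
    tau2: float      # (g/dL)^2 between-survey variance
    tau: float       # g/dL
    Q: float         # Cochran heterogeneity statistic (fixed-effect weights)
    df: int
    k: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if self.df != self.k - 1:
            raise ValueError("df must equal k - 1")


def reml_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of tau2 (up to an additive constant)."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return -0.5 * (
        np.sum(np.log(v + tau2))
        + np.log(np.sum(w))
        + np.sum(w * (y - mu) ** 2)
    )


def reml_tau2(
    y: Sequence[float],
    v: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[float, bool]:
    """REML estimate of the between-survey variance.

    Fisher scoring on tau2 with projection onto [0, inf); falls back to
    bounded scalar maximisation of the restricted likelihood if scoring
    fails to settle.  Returns (tau2_hat, converged).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.size < 2:
        raise ValueError("need k >= 2 estimates")
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")

    tau2 = max(np.var(y, ddof=1) - np.mean(v), 0.0)  # DL-style start
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw, sw2, sw3 = np.sum(w), np.sum(w**2), np.sum(w**3)
        mu = np.sum(w * y) / sw
        r2 = (y - mu) ** 2
        score = 0.5 * (np.sum(w**2 * r2) - sw + sw2 / sw)
        # expected information of the restricted likelihood in tau2
        info = 0.5 * (sw2 - 2.0 * sw3 / sw + (sw2 / sw) ** 2)
        if info <= 0:
            break
        step = score / info
        new = tau2 + step
        if new < 0.0:
            new = tau2 / 2.0 if tau2 > 0 else 0.0
        if abs(new - tau2) < tol * (1.0 + tau2):
            # scoring fixed point; accept if it is a boundary or score ~ 0
            tau2 = max(new, 0.0)
            return tau2, True
        tau2 = max(new, 0.0)

    # fallback: direct bounded maximisation
    hi = max(np.var(y, ddof=1) * 10.0, np.max(v) * 10.0, 1.0)
    res = optimize.minimize_scalar(
        lambda t: -reml_loglik(t, y, v), bounds=(0.0, hi), method="bounded",
        options={"xatol": tol},
    )
    return float(max(res.x, 0.0)), bool(res.success)


def cochran_q(estimates: Sequence[QuantileEstimate]) -> tuple[float, int]:
    """Cochran's Q (fixed-effect weights 1/v_i) and its degrees of freedom."""
    if len(estimates) < 2:
        raise ValueError("need k >= 2 estimates")
    y = np.array([e.q_hat for e in estimates])
    v = np.array([e.se_q**2 for e in estimates])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be positive")
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    return Q, len(estimates) - 1


def reml_pool(
    estimates: Sequence[QuantileEstimate],
    level: float = 0.95,
    tau2_override: float | None = None,
) -> MetaResult:
    """Pool survey quantile estimates under the random-effects model.

    ``tau2_override`` fixes tau2 (0 gives the fixed-effect limit, used
    by oracle checks); otherwise tau2 is the REML estimate.
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("need k >= 2 estimates to pool")
    y = np.array([e.q_hat for e in estimates])
    v = np.array([e.se_q**2 for e in estimates])
    if np.any(v <= 0):
        raise ValueError("all se_q must be positive")

    if tau2_override is not None:
        if tau2_override < 0:
            raise ValueError("tau2_override must be nonnegative")
        tau2, converged = float(tau2_override), True
    else:
        tau2, converged = reml_tau2(y, v)
        if not converged:
            raise RuntimeError("REML estimation of tau2 did not converge")

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sum(w) ** -0.5)
    z = stats.norm.ppf(0.5 + level / 2.0)
    Q, df = cochran_q(estimates)
    return MetaResult(
        mu_hat=mu, se_mu=se_mu,
        ci_low=mu - z * se_mu, ci_high=mu + z * se_mu,
        tau2=tau2, tau=float(np.sqrt(tau2)),
        Q=Q, df=df, k=k, converged=converged,
    )


def forest_table(
    estimates: Sequence[QuantileEstimate],
    pooled: MetaResult,
    sort_by: str = "survey_id",
) -> pd.DataFrame:
    """Forest-plot data: one row per survey plus a pooled row.

    ``sort_by`` is any per-survey column ('survey_id', 'estimate', 'n').
    """
    rows = [
        {
            "label": e.survey_id,
            "estimate": e.q_hat,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "n": e.n,
            "pooled": False,
        }
        for e in estimates
    ]
    df = pd.DataFrame(rows)
    key = {"survey_id": "label"}.get(sort_by, sort_by)
    if key not in df.columns:
        raise ValueError(f"unknown sort key {sort_by!r}")
    df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
    pooled_row = pd.DataFrame(
        [{
            "label": f"POOLED (k={pooled.k}, tau={pooled.tau:.3f}, "
                     f"Q/df={pooled.Q:.1f}/{pooled.df})",
            "estimate": pooled.mu_hat,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "n": int(sum(e.n for e in estimates)),
            "pooled": True,
        }]
    )
    return pd.concat([df, pooled_row], ignore_index=True)


def plot_forest(table: pd.DataFrame, path, reference: float | None = None):
    """Optional forest plot (vector format); requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.32 * len(table) + 1.5))
    ypos = np.arange(len(table))[::-1]
    for y, (_, row) in zip(ypos, table.iterrows()):
        marker = "D" if row["pooled"] else "s"
        ax.plot([row["ci_low"], row["ci_high"]], [y, y], color="k", lw=1)
        ax.plot(row["estimate"], y, marker, color="k", ms=5)
    if reference is not None:
        ax.axvline(reference, ls="--", color="gray", lw=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["label"])
    ax.set_xlabel("Hb fifth percentile (g/dL)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
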