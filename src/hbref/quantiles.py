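"""Survey-specific quantile estimation with Woodruff-type confidence intervals.

The survey-specific fifth percentile of Hb is estimated by univariate
quantile ranking (inverse empirical CDF).  Its confidence interval is
obtained by the Woodruff construction: a Wald interval on the *proportion*
below the quantile, SE(p_hat) = sqrt(p(1-p)/n) at a design effect of 1
(simple random sampling), is mapped through the empirical quantile
function back to the Hb scale.  The reported SE is the CI width divided
by 2z, which is how a forest-plot meta-analysis consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import IndividualRecord

__all__ = [
    "QuantileEstimate",
    "QuantileCIUndefinedError",
    "empirical_quantile",
    "quantile_ci",
    "survey_quantiles",
]


class QuantileCIUndefinedError(ValueError):
    """The Wald proportion bounds leave (0, 1); n is too small for the CI."""


@dataclass(frozen=True)
class QuantileEstimate:
    """A survey's quantile of Hb with Woodruff CI."""

    survey_id: str
    p: float
    q_hat: float     # g/dL
    se_q: float      # g/dL
    ci_low: float    # g/dL
    ci_high: float   # g/dL
    n: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must be in (0, 1)")
        if not (self.ci_low <= self.q_hat <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def empirical_quantile(x: Sequence[float], p: float) -> float:
    """Inverse-ECDF (left-continuous, order statistic ceil(n*p)) quantile.

    The convention is fixed so that the Woodruff proportion-to-quantile
    mapping is self-consistent; ties (e.g. 0.1 g/dL instrument
    resolution) follow the same order-statistic rule, no jittering.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    return float(np.quantile(x, p, method="inverted_cdf"))


def quantile_ci(
    x: Sequence[float],
    p: float,
    level: float = 0.95,
    survey_id: str = "",
) -> QuantileEstimate:
    """Quantile point estimate with Woodruff (Wald-on-proportion) CI.

    Raises :class:`QuantileCIUndefinedError` when p -/+ z*SE leaves
    (0, 1): the sample is too small for the interval to be defined, and
    truncating would understate uncertainty.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se_p = np.sqrt(p * (1.0 - p) / n)
    p_lo, p_hi = p - z * se_p, p + z * se_p
    if p_lo <= 0.0 or p_hi >= 1.0:
        raise QuantileCIUndefinedError(
            f"proportion bounds ({p_lo:.4f}, {p_hi:.4f}) leave (0,1) at n={n}"
        )
    xs = np.sort(x)
    q_hat = _orderstat(xs, p)
    ci_low = _orderstat(xs, p_lo)
    ci_high = _orderstat(xs, p_hi)
    se_q = (ci_high - ci_low) / (2.0 * z)
    return QuantileEstimate(
        survey_id=survey_id, p=p, q_hat=q_hat, se_q=se_q,
        ci_low=ci_low, ci_high=ci_high, n=int(n),
    )


def _orderstat(xs: np.ndarray, p: float) -> float:
    """x_(ceil(n*p)) on a pre-sorted array (1-indexed order statistic)."""
    n = xs.size
    k = int(np.ceil(n * p))
    k = min(max(k, 1), n)
    return float(xs[k - 1])


def survey_quantiles(
    records: Sequence[IndividualRecord],
    p: float = 0.05,
    level: float = 0.95,
) -> list[QuantileEstimate]:
    """Per-survey quantile estimates, ordered by survey id."""
    by_survey: dict[str, list[float]] = {}
    for r in records:
        by_survey.setdefault(r.survey_id, []).append(r.hb)
    return [
        quantile_ci(by_survey[sid], p, level, survey_id=sid)
        for sid in sorted(by_survey)
    ]
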