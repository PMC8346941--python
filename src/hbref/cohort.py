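"""Apparently-healthy case definition, anemia classification, data-loss accounting.

Historical anemia cutoffs are lower reference limits of a *healthy*
distribution, so the analysis first strips out individuals whose
biomarkers indicate iron deficiency, vitamin A deficiency, inflammation
or malaria — conditions that depress Hb and would otherwise drag the
fifth percentile down.  The case definition is:

* iron replete: ferritin >= 12 ng/mL (children) / >= 15 ng/mL (women);
* no vitamin A deficiency: RBP or retinol >= 20.1 ug/dL, where measured;
* no inflammation: CRP <= 0.5 mg/dL or AGP <= 1 g/L (both must pass
  when both are measured);
* no malaria, where measured.

All comparisons are inclusive on the healthy side.  "Where measured"
means an unmeasured optional marker never excludes anyone; ferritin and
at least one inflammation marker are mandatory.  Ferritin and vitamin A
are used unadjusted for inflammation, because inflamed individuals are
excluded outright.  Surveys retaining fewer than ``min_healthy_per_survey``
(default 100) healthy individuals are dropped entirely to keep the
percentile estimates stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .records import IndividualRecord

__all__ = [
    "HealthyCriteria",
    "CohortReport",
    "MissingBiomarkerError",
    "EmptyCohortError",
    "is_healthy",
    "build_healthy_cohort",
    "classify_anemia",
    "anemia_prevalence",
    "sensitivity_grid",
    "WHO_ANEMIA_CUTOFFS",
]

#: WHO Hb anemia cutoffs, g/dL (strict '<' comparisons)
WHO_ANEMIA_CUTOFFS = {"child": 11.0, "woman": 12.0}


class MissingBiomarkerError(ValueError):
    """A mandatory biomarker (ferritin, or both CRP and AGP) is absent."""


class EmptyCohortError(RuntimeError):
    """Every survey was dropped; no healthy cohort remains."""


@dataclass(frozen=True)
class HealthyCriteria:
    """Thresholds defining the apparently healthy subpopulation."""

    ferritin_min_child: float = 12.0   # ng/mL
    ferritin_min_woman: float = 15.0   # ng/mL
    vita_min: float = 20.1             # ug/dL
    crp_max: float = 0.5               # mg/dL
    agp_max: float = 1.0               # g/L
    require_no_malaria: bool = True
    min_healthy_per_survey: int = 100

    def __post_init__(self) -> None:
        for name in ("ferritin_min_child", "ferritin_min_woman",
                     "vita_min", "crp_max", "agp_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_healthy_per_survey < 1:
            raise ValueError("min_healthy_per_survey must be >= 1")

    def ferritin_min(self, group: str) -> float:
        return self.ferritin_min_child if group == "child" else self.ferritin_min_woman


@dataclass(frozen=True)
class CohortReport:
    """Data-loss accounting for the healthy-cohort filter."""

    n_total: int
    n_healthy: int
    pct_excluded: float
    surveys_dropped: tuple[str, ...]
    per_survey_counts: pd.DataFrame = field(compare=False)

    def __post_init__(self) -> None:
        if self.n_healthy > self.n_total:
            raise ValueError("n_healthy cannot exceed n_total")


def is_healthy(rec: IndividualRecord, crit: HealthyCriteria) -> bool:
    """Apparently-healthy flag; unmeasured optional markers never exclude."""
    if rec.ferritin is None:
        raise MissingBiomarkerError(
            f"ferritin required for healthy classification (survey {rec.survey_id})"
        )
    if rec.crp is None and rec.agp is None:
        raise MissingBiomarkerError(
            f"at least one inflammation marker (crp or agp) required "
            f"(survey {rec.survey_id})"
        )
    if rec.ferritin < crit.ferritin_min(rec.group):
        return False
    if rec.vita is not None and rec.vita < crit.vita_min:
        return False
    if rec.crp is not None and rec.crp > crit.crp_max:
        return False
    if rec.agp is not None and rec.agp > crit.agp_max:
        return False
    if crit.require_no_malaria and rec.malaria == "positive":
        return False
    return True


def build_healthy_cohort(
    records: Sequence[IndividualRecord],
    crit: HealthyCriteria | None = None,
) -> tuple[list[IndividualRecord], CohortReport]:
    """Healthy subset plus data-loss report.

    Surveys whose healthy count falls below ``crit.min_healthy_per_survey``
    are removed entirely (their healthy members included) and listed in
    the report.
    """
    if not records:
        raise ValueError("build_healthy_cohort requires a nonempty record list")
    crit = crit or HealthyCriteria()

    totals: dict[str, int] = {}
    healthy_by_survey: dict[str, list[IndividualRecord]] = {}
    for r in records:
        totals[r.survey_id] = totals.get(r.survey_id, 0) + 1
        healthy_by_survey.setdefault(r.survey_id, [])
        if is_healthy(r, crit):
            healthy_by_survey[r.survey_id].append(r)

    dropped = tuple(
        sid for sid in sorted(totals)
        if len(healthy_by_survey[sid]) < crit.min_healthy_per_survey
    )
    healthy = [
        r for sid in sorted(totals)
        if sid not in dropped
        for r in healthy_by_survey[sid]
    ]

    per_survey = pd.DataFrame(
        {
            "survey_id": sorted(totals),
            "n_total": [totals[s] for s in sorted(totals)],
            "n_healthy": [len(healthy_by_survey[s]) for s in sorted(totals)],
            "dropped": [s in dropped for s in sorted(totals)],
        }
    )
    n_total = len(records)
    report = CohortReport(
        n_total=n_total,
        n_healthy=len(healthy),
        pct_excluded=100.0 * (1.0 - len(healthy) / n_total),
        surveys_dropped=dropped,
        per_survey_counts=per_survey,
    )
    if not healthy:
        raise EmptyCohortError(
            f"no survey retained >= {crit.min_healthy_per_survey} healthy "
            f"individuals ({len(dropped)} surveys dropped)"
        )
    return healthy, report


def classify_anemia(rec: IndividualRecord) -> bool:
    """WHO anemia flag: Hb < 11.0 g/dL (children) / < 12.0 g/dL (women)."""
    return rec.hb < WHO_ANEMIA_CUTOFFS[rec.group]


def anemia_prevalence(records: Sequence[IndividualRecord]) -> float:
    """Fraction anemic under the WHO cutoffs."""
    if not records:
        raise ValueError("empty record list")
    return sum(classify_anemia(r) for r in records) / len(records)


def sensitivity_grid(
    records: Sequence[IndividualRecord],
    base: HealthyCriteria,
    grid: Sequence[HealthyCriteria],
    p: float = 0.05,
    level: float = 0.95,
) -> pd.DataFrame:
    """Pooled-P5 sensitivity ladder over alternative healthy criteria.

    For each criteria set the full cohort -> per-survey quantile -> REML
    pipeline is run; rows tabulate analytic n, % of the original sample,
    number of retained surveys, and the pooled fifth percentile with CI
    (the layout of a threshold-sensitivity table).
    """
    from .meta import reml_pool
    from .quantiles import survey_quantiles

    if not grid:
        raise ValueError("grid must be nonempty")
    n_original = len(records)
    rows = []
    for i, crit in enumerate(grid):
        healthy, report = build_healthy_cohort(records, crit)
        ests = survey_quantiles(healthy, p=p, level=level)
        pooled = reml_pool(ests, level=level)
        rows.append(
            {
                "criteria_index": i,
                "is_base": crit == base,
                "ferritin_min_child": crit.ferritin_min_child,
                "ferritin_min_woman": crit.ferritin_min_woman,
                "vita_min": crit.vita_min,
                "n_analytic": report.n_healthy,
                "pct_of_original": 100.0 * report.n_healthy / n_original,
                "k_surveys": pooled.k,
                "p5": pooled.mu_hat,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "tau": pooled.tau,
            }
        )
    return pd.DataFrame(rows)
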