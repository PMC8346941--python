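"""End-to-end composition of the analysis stages.

The fifth-percentile pipeline is: adjust Hb (altitude, smoking) ->
apparently-healthy cohort -> per-survey quantile with Woodruff CI ->
REML random-effects pooling.  Each stage's record counts in and out are
collected so data loss is first-class output, and a run manifest makes
any run reproducible from (config, seed, input digest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .adjust import adjust_records
from .cohort import CohortReport, anemia_prevalence, build_healthy_cohort
from .config import config_digest, criteria_from_config, policy_from_config
from .meta import MetaResult, forest_table, reml_pool
from .quantiles import QuantileEstimate, survey_quantiles
from .records import IndividualRecord

__all__ = ["P5Result", "run_p5_pipeline", "write_manifest"]


@dataclass(frozen=True)
class P5Result:
    """Everything the fifth-percentile pipeline produces."""

    pooled: MetaResult
    estimates: list[QuantileEstimate]
    report: CohortReport
    anemia_prev_all: float
    anemia_prev_healthy: float
    stage_log: list[str] = field(default_factory=list)


def run_p5_pipeline(
    records: Sequence[IndividualRecord],
    cfg: dict,
    adjust: bool = True,
) -> P5Result:
    """Adjust -> cohort -> survey quantiles -> REML pool."""
    log: list[str] = [f"input: {len(records)} records"]
    if adjust and cfg["adjustment"]["enabled"]:
        records = adjust_records(records, policy_from_config(cfg))
        log.append("adjustment: altitude + smoking applied")
    else:
        records = list(records)
        log.append("adjustment: skipped")

    crit = criteria_from_config(cfg)
    healthy, report = build_healthy_cohort(records, crit)
    log.append(
        f"cohort: {report.n_healthy}/{report.n_total} healthy "
        f"({report.pct_excluded:.1f}% excluded), "
        f"{len(report.surveys_dropped)} survey(s) dropped"
    )

    p = float(cfg["quantile"]["p"])
    level = float(cfg["quantile"]["level"])
    estimates = survey_quantiles(healthy, p=p, level=level)
    log.append(f"survey_quantile: {len(estimates)} surveys at p={p}")

    pooled = reml_pool(estimates, level=level)
    log.append(
        f"meta: pooled={pooled.mu_hat:.3f} g/dL "
        f"(tau={pooled.tau:.3f}, Q/df={pooled.Q:.1f}/{pooled.df})"
    )
    return P5Result(
        pooled=pooled,
        estimates=estimates,
        report=report,
        anemia_prev_all=anemia_prevalence(records),
        anemia_prev_healthy=anemia_prevalence(healthy),
        stage_log=log,
    )


def write_manifest(
    out_dir: Path,
    cfg: dict,
    seed: int,
    outputs: Sequence[Path],
    input_path: Path | None = None,
) -> Path:
    """Run manifest: config digest + seed + input digest fully determine a re-run."""
    manifest = {
        "package": "hbref",
        "version": __version__,
        "config_sha256": config_digest(cfg),
        "seed": seed,
        "input_sha256": _file_digest(input_path) if input_path else None,
        "outputs": [str(Path(p).name) for p in outputs],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
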