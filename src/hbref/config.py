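"""YAML configuration: defaults, loading, and object construction.

A single config file drives end-to-end runs.  Sections:

``columns``     column-alias map for CSV ingestion (file name -> canonical)
``adjustment``  altitude/smoking policy coefficients
``healthy``     apparently-healthy thresholds and the survey-size floor
``quantile``    analysis quantile and CI level
``meta``        REML tolerances
``lqmm``        quadrature nodes, restarts, age-unit handling
``spline``      knot quantiles, bootstrap replicates
``synthetic``   generator overrides (group picks child/woman defaults)

Any subset may appear in a user file; unspecified keys keep defaults.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .adjust import AdjustmentPolicy
from .cohort import HealthyCriteria

__all__ = [
    "DEFAULTS",
    "load_config",
    "criteria_from_config",
    "policy_from_config",
    "config_digest",
]

DEFAULTS: dict = {
    "columns": {},  # e.g. {"hgb": "hb", "ft": "ferritin"}
    "adjustment": {
        "enabled": True,
        "altitude_coeff_linear": -0.032,
        "altitude_coeff_quad": 0.022,
        "altitude_floor": 1000.0,
        "smoking_decrement": 0.3,
        "altitude_unit_factor": 0.0032808,
    },
    "healthy": {
        "ferritin_min_child": 12.0,
        "ferritin_min_woman": 15.0,
        "vita_min": 20.1,
        "crp_max": 0.5,
        "agp_max": 1.0,
        "require_no_malaria": True,
        "min_healthy_per_survey": 100,
    },
    "quantile": {"p": 0.05, "level": 0.95},
    "meta": {"tol": 1e-8, "max_iter": 200},
    "lqmm": {
        "n_nodes": 11,
        "restarts": 3,
        "seed": 0,
        "child_age_in_years": True,
    },
    "spline": {
        "knot_quantiles": [0.05, 0.275, 0.50, 0.725, 0.95],
        "bootstrap_B": 5000,
        "level": 0.95,
        "seed": 0,
    },
    "synthetic": {"group": "child", "seed": 0},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults merged with a YAML file and programmatic overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def criteria_from_config(cfg: dict) -> HealthyCriteria:
    h = cfg["healthy"]
    return HealthyCriteria(
        ferritin_min_child=float(h["ferritin_min_child"]),
        ferritin_min_woman=float(h["ferritin_min_woman"]),
        vita_min=float(h["vita_min"]),
        crp_max=float(h["crp_max"]),
        agp_max=float(h["agp_max"]),
        require_no_malaria=bool(h["require_no_malaria"]),
        min_healthy_per_survey=int(h["min_healthy_per_survey"]),
    )


def policy_from_config(cfg: dict) -> AdjustmentPolicy:
    a = cfg["adjustment"]
    return AdjustmentPolicy(
        altitude_coeff_linear=float(a["altitude_coeff_linear"]),
        altitude_coeff_quad=float(a["altitude_coeff_quad"]),
        altitude_floor=float(a["altitude_floor"]),
        smoking_decrement=float(a["smoking_decrement"]),
        altitude_unit_factor=float(a["altitude_unit_factor"]),
    )


def config_digest(cfg: dict) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
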