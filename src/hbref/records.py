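"""Data model and delimited-text I/O for multi-survey hemoglobin records.

One row = one individual's biomarker panel within a household nutrition
survey.  Two target groups are supported: preschool children (age in
months, 6-59) and nonpregnant women (age in years, 15-49).  Units follow
the conventional reporting scale for these biomarkers:

=========  ==========  =============================================
field      unit        meaning
=========  ==========  =============================================
hb         g/dL        hemoglobin concentration
ferritin   ng/mL       iron-store biomarker
vita       ug/dL       vitamin A biomarker (RBP or retinol)
crp        mg/dL       C-reactive protein (acute inflammation)
agp        g/L         alpha-1-acid glycoprotein (chronic inflammation)
stfr       mg/L        soluble transferrin receptor
altitude   m           residence altitude above sea level
=========  ==========  =============================================

Conversion factors to SI-style units are provided as documented module
constants and are never applied implicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IndividualRecord",
    "SurveyMeta",
    "RecordValidationError",
    "read_records",
    "write_records",
    "summarize_surveys",
    "records_to_frame",
    "frame_to_records",
    "HB_GDL_TO_GL",
    "FERRITIN_NGML_TO_UGL",
    "VITA_UGDL_TO_UMOLL",
    "CRP_MGDL_TO_MGL",
]

# Unit conversion factors (multiply by these; never applied implicitly).
HB_GDL_TO_GL = 10.0          # hemoglobin g/dL -> g/L
FERRITIN_NGML_TO_UGL = 1.0   # ferritin ng/mL -> ug/L
VITA_UGDL_TO_UMOLL = 0.0349  # retinol/RBP ug/dL -> umol/L
CRP_MGDL_TO_MGL = 10.0       # CRP mg/dL -> mg/L

GROUPS = frozenset({"child", "woman"})
SEXES = frozenset({"male", "female"})
TRISTATE = frozenset({"positive", "negative", "unmeasured"})
BLOOD_SOURCES = frozenset({"venous", "capillary", "unknown"})
HB_METHODS = frozenset(
    {"analyzer", "hemocue_hbb", "hemocue_201", "hemocue_301", "unknown"}
)

CHILD_AGE_MONTHS = (6.0, 59.0)
WOMAN_AGE_YEARS = (15.0, 49.0)

#: optional nonnegative numeric fields
_OPTIONAL_NUMERIC = ("ferritin", "vita", "crp", "agp", "stfr", "altitude")

#: canonical CSV column order
CSV_COLUMNS = (
    "survey_id", "group", "age", "sex", "hb", "ferritin", "vita", "crp",
    "agp", "malaria", "stfr", "altitude", "smoker", "blood_source",
    "hb_method", "hb_adjusted",
)

MANDATORY_COLUMNS = ("survey_id", "age", "hb")


class RecordValidationError(ValueError):
    """A survey row violates a hard invariant of the data model."""


@dataclass(frozen=True)
class IndividualRecord:
    """One person's biomarker panel plus survey membership."""

    survey_id: str
    group: str                  # 'child' | 'woman'
    age: float                  # months (child) or years (woman)
    sex: str                    # 'male' | 'female'
    hb: float                   # g/dL
    ferritin: float | None = None   # ng/mL
    vita: float | None = None       # ug/dL (RBP or retinol)
    crp: float | None = None        # mg/dL
    agp: float | None = None        # g/L
    malaria: str = "unmeasured"     # tri-state
    stfr: float | None = None       # mg/L
    altitude: float | None = None   # meters
    smoker: str = "unmeasured"      # tri-state
    blood_source: str = "unknown"
    hb_method: str = "unknown"
    hb_adjusted: bool = False       # set by the adjustment stage

    def __post_init__(self) -> None:
        if not self.survey_id:
            raise RecordValidationError("survey_id must be nonempty")
        if self.group not in GROUPS:
            raise RecordValidationError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise RecordValidationError(f"unknown sex {self.sex!r}")
        if not (0.0 < self.hb < 25.0):
            raise RecordValidationError(
                f"hb must be in (0, 25) g/dL, got {self.hb!r}"
            )
        if self.group == "child":
            lo, hi = CHILD_AGE_MONTHS
            if not (lo <= self.age <= hi):
                raise RecordValidationError(
                    f"child age must be in [{lo:g}, {hi:g}] months, got {self.age!r}"
                )
        else:
            lo, hi = WOMAN_AGE_YEARS
            if not (lo <= self.age <= hi):
                raise RecordValidationError(
                    f"woman age must be in [{lo:g}, {hi:g}] years, got {self.age!r}"
                )
            if self.sex != "female":
                raise RecordValidationError("woman records must have sex=female")
        for name in _OPTIONAL_NUMERIC:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RecordValidationError(f"{name} must be nonnegative, got {v!r}")
        if self.malaria not in TRISTATE:
            raise RecordValidationError(f"malaria must be tri-state, got {self.malaria!r}")
        if self.smoker not in TRISTATE:
            raise RecordValidationError(f"smoker must be tri-state, got {self.smoker!r}")
        if self.blood_source not in BLOOD_SOURCES:
            raise RecordValidationError(f"unknown blood_source {self.blood_source!r}")
        if self.hb_method not in HB_METHODS:
            raise RecordValidationError(f"unknown hb_method {self.hb_method!r}")

    def with_hb(self, hb: float, adjusted: bool = True) -> "IndividualRecord":
        return replace(self, hb=hb, hb_adjusted=adjusted)


@dataclass(frozen=True)
class SurveyMeta:
    """Per-survey availability flags derived from observed missingness."""

    survey_id: str
    n_records: int
    measures_vita: bool
    measures_malaria: bool
    has_altitude: bool
    has_smoking: bool
    country_label: str = ""


def _parse_optional_float(raw: str | None, field: str) -> float | None:
    if raw is None:
        return None
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise RecordValidationError(f"{field} is not numeric: {raw!r}") from None


def _parse_tristate(raw: str | None, field: str) -> str:
    if raw is None or raw.strip() == "":
        return "unmeasured"
    v = raw.strip().lower()
    if v in TRISTATE:
        return v
    if v in {"1", "true", "yes"}:
        return "positive"
    if v in {"0", "false", "no"}:
        return "negative"
    raise RecordValidationError(f"{field} must be positive/negative/empty, got {raw!r}")


def read_records(
    path: str | Path,
    group: str,
    aliases: dict[str, str] | None = None,
    *,
    return_diagnostics: bool = False,
):
    """Read validated records from a RFC-4180 CSV file.

    Parameters
    ----------
    path
        CSV file with a header row.  Missing optional values are empty
        cells; sentinel numerics (e.g. ``-9``) are rejected, never
        reinterpreted as missing.
    group
        Declared target group for the file ('child' or 'woman').  If a
        ``group`` column is present, rows must agree with the declared
        group; otherwise the declared group is assigned.
    aliases
        Optional map from file column names to canonical field names.
    return_diagnostics
        When true, return ``(records, diagnostics)`` where diagnostics is
        a list of ``(line_number, message)`` for every rejected row.
        Every input row is either accepted or yields exactly one
        diagnostic.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    aliases = aliases or {}

    records: list[IndividualRecord] = []
    diagnostics: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RecordValidationError(f"{path}: empty file, no header")
        colmap = {aliases.get(c, c): c for c in reader.fieldnames}
        missing = [c for c in MANDATORY_COLUMNS if c not in colmap]
        if missing:
            raise RecordValidationError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_row_to_record(row, colmap, group))
            except RecordValidationError as exc:
                diagnostics.append((lineno, str(exc)))
    if return_diagnostics:
        return records, diagnostics
    if diagnostics:
        preview = "; ".join(f"line {ln}: {msg}" for ln, msg in diagnostics[:5])
        raise RecordValidationError(
            f"{path}: {len(diagnostics)} invalid row(s): {preview}"
        )
    return records


def _row_to_record(
    row: dict[str, str], colmap: dict[str, str], group: str
) -> IndividualRecord:
    def get(field: str) -> str | None:
        col = colmap.get(field)
        return row.get(col) if col is not None else None

    row_group = (get("group") or "").strip() or group
    if row_group != group:
        raise RecordValidationError(
            f"row group {row_group!r} does not match declared group {group!r}"
        )
    age = _parse_optional_float(get("age"), "age")
    hb = _parse_optional_float(get("hb"), "hb")
    if age is None:
        raise RecordValidationError("age is missing")
    if hb is None:
        raise RecordValidationError("hb is missing")
    sex = (get("sex") or "").strip().lower()
    if not sex:
        if group == "woman":
            sex = "female"
        else:
            raise RecordValidationError("sex is missing (required for children)")
    adj_raw = (get("hb_adjusted") or "").strip().lower()
    return IndividualRecord(
        survey_id=(get("survey_id") or "").strip(),
        group=group,
        age=age,
        sex=sex,
        hb=hb,
        ferritin=_parse_optional_float(get("ferritin"), "ferritin"),
        vita=_parse_optional_float(get("vita"), "vita"),
        crp=_parse_optional_float(get("crp"), "crp"),
        agp=_parse_optional_float(get("agp"), "agp"),
        malaria=_parse_tristate(get("malaria"), "malaria"),
        stfr=_parse_optional_float(get("stfr"), "stfr"),
        altitude=_parse_optional_float(get("altitude"), "altitude"),
        smoker=_parse_tristate(get("smoker"), "smoker"),
        blood_source=(get("blood_source") or "").strip() or "unknown",
        hb_method=(get("hb_method") or "").strip() or "unknown",
        hb_adjusted=adj_raw in {"1", "true", "yes"},
    )


def write_records(records: Sequence[IndividualRecord], path: str | Path) -> None:
    """Write records as canonical CSV (UTF-8, header row, empty = missing)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.survey_id, r.group, _fmt(r.age), r.sex, _fmt(r.hb),
                    _fmt(r.ferritin), _fmt(r.vita), _fmt(r.crp), _fmt(r.agp),
                    "" if r.malaria == "unmeasured" else r.malaria,
                    _fmt(r.stfr), _fmt(r.altitude),
                    "" if r.smoker == "unmeasured" else r.smoker,
                    r.blood_source, r.hb_method,
                    "true" if r.hb_adjusted else "",
                ]
            )


def _fmt(v: float | None) -> str:
    if v is None:
        return ""
    return format(v, ".10g")


def summarize_surveys(records: Sequence[IndividualRecord]) -> list[SurveyMeta]:
    """One :class:`SurveyMeta` per distinct survey, flags from missingness.

    A survey "measures" a field iff at least one of its records has it
    nonmissing.
    """
    if not records:
        raise ValueError("summarize_surveys requires a nonempty record list")
    by_survey: dict[str, list[IndividualRecord]] = {}
    for r in records:
        by_survey.setdefault(r.survey_id, []).append(r)
    metas = []
    for sid in sorted(by_survey):
        recs = by_survey[sid]
        metas.append(
            SurveyMeta(
                survey_id=sid,
                n_records=len(recs),
                measures_vita=any(r.vita is not None for r in recs),
                measures_malaria=any(r.malaria != "unmeasured" for r in recs),
                has_altitude=any(r.altitude is not None for r in recs),
                has_smoking=any(r.smoker != "unmeasured" for r in recs),
            )
        )
    return metas


def records_to_frame(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    """Records as a pandas DataFrame (missing -> NaN / 'unmeasured')."""
    cols = {f.name: [getattr(r, f.name) for r in records]
            for f in dc_fields(IndividualRecord)}
    return pd.DataFrame(cols)


def frame_to_records(frame: pd.DataFrame) -> list[IndividualRecord]:
    """Validated records from a DataFrame with canonical column names."""
    recs = []
    defaults = {f.name: f.default for f in dc_fields(IndividualRecord)}
    for row in frame.itertuples(index=False):
        d = row._asdict()
        kwargs = {}
        for name, default in defaults.items():
            v = d.get(name, default)
            if pd.isna(v):
                v = None if name in _OPTIONAL_NUMERIC else default
            kwargs[name] = v
        kwargs["survey_id"] = str(kwargs["survey_id"])
        recs.append(IndividualRecord(**kwargs))
    return recs
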