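"""Altitude and smoking adjustment of measured hemoglobin.

Residence at altitude raises Hb through hypoxia-driven erythropoiesis,
and smoking raises it through carboxyhemoglobin formation; both shift
measured Hb upward relative to the sea-level nonsmoking physiology that
anemia cutoffs describe.  The standard field correction subtracts

    c(A) = -0.032*A + 0.022*A**2          [g/dL]

where ``A`` is altitude in thousands of feet, applied only at or above
1000 m (below that the correction is within instrument noise and is
conventionally skipped), and subtracts a flat 0.3 g/dL from women who
smoke.  Children are never smoking-adjusted.  Records that lack
altitude or smoking data pass through unchanged, mirroring the
survey-by-survey availability of those variables.

Coefficients live in :class:`AdjustmentPolicy` so alternative lookup
tables can be swapped in; setting every coefficient to zero makes both
operations the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records import IndividualRecord

__all__ = [
    "AdjustmentPolicy",
    "AlreadyAdjustedError",
    "adjust_altitude",
    "adjust_smoking",
    "adjust_records",
]

#: thousands of feet per meter
METERS_TO_KFT = 0.0032808


class AlreadyAdjustedError(RuntimeError):
    """Raised when adjustment is applied to an already-adjusted record."""


@dataclass(frozen=True)
class AdjustmentPolicy:
    """Coefficients governing the altitude and smoking corrections."""

    altitude_coeff_linear: float = -0.032   # g/dL per thousand feet
    altitude_coeff_quad: float = 0.022      # g/dL per (thousand feet)^2
    altitude_floor: float = 1000.0          # meters; apply only at/above
    smoking_decrement: float = 0.3          # g/dL subtracted for women who smoke
    altitude_unit_factor: float = METERS_TO_KFT

    def __post_init__(self) -> None:
        if self.altitude_floor < 0:
            raise ValueError("altitude_floor must be >= 0")
        if self.smoking_decrement < 0:
            raise ValueError("smoking_decrement must be >= 0")

    def altitude_correction(self, altitude_m: float) -> float:
        """c(A) in g/dL for a given altitude in meters (no floor check)."""
        a = altitude_m * self.altitude_unit_factor
        return self.altitude_coeff_linear * a + self.altitude_coeff_quad * a * a


def adjust_altitude(
    hb: float, altitude: float | None, policy: AdjustmentPolicy
) -> float:
    """Altitude-corrected Hb; pass-through below the floor or without data."""
    if hb <= 0:
        raise ValueError("hb must be positive")
    if altitude is None:
        return hb
    if altitude < 0:
        raise ValueError(f"negative altitude: {altitude!r}")
    if altitude < policy.altitude_floor:
        return hb
    adjusted = hb - policy.altitude_correction(altitude)
    if adjusted <= 0:
        raise ValueError(
            f"altitude adjustment drove hb nonpositive ({adjusted:.3f} g/dL)"
        )
    return adjusted


def adjust_smoking(
    hb: float, smoker: str, group: str, policy: AdjustmentPolicy
) -> float:
    """Smoking-corrected Hb for women; children and nonsmokers unchanged."""
    if hb <= 0:
        raise ValueError("hb must be positive")
    if group == "woman" and smoker == "positive":
        adjusted = hb - policy.smoking_decrement
        if adjusted <= 0:
            raise ValueError(
                f"smoking adjustment drove hb nonpositive ({adjusted:.3f} g/dL)"
            )
        return adjusted
    return hb


def adjust_records(
    records: Sequence[IndividualRecord],
    policy: AdjustmentPolicy | None = None,
) -> list[IndividualRecord]:
    """Apply altitude then smoking adjustment to every record, once.

    Returned records carry ``hb_adjusted=True``; feeding an adjusted
    record back in raises :class:`AlreadyAdjustedError` so the correction
    can never be applied twice.
    """
    policy = policy or AdjustmentPolicy()
    out = []
    for r in records:
        if r.hb_adjusted:
            raise AlreadyAdjustedError(
                f"record in survey {r.survey_id} is already adjusted"
            )
        hb = adjust_altitude(r.hb, r.altitude, policy)
        hb = adjust_smoking(hb, r.smoker, r.group, policy)
        out.append(r.with_hb(hb, adjusted=True))
    return out
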