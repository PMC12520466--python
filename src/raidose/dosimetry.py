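"""Blood absorbed dose and maximum tolerated activity (MTA).

The blood absorbed dose per unit administered activity is computed with the
simplified two-term coefficient

    d = D_blood / A0 = (15.12 / BVL + 0.0188 / wt^(2/3)) · τ   [mGy/MBq]

where BVL is the blood volume in mL, wt the body weight in kg and τ the
whole-body residence time in hours.  The first term is the beta self-dose
to blood (the whole-body beta coefficient scaled by the 14% blood share of
the whole-body residence time); the second is the penetrating-photon
contribution with its body-size scaling.  The MTA is the administered
activity at which the estimated blood dose reaches a safety limit,
additionally constrained so that the retained whole-body activity at 48 h
stays under 4.4 GBq.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

from .core import DEFAULT_CONSTANTS, DosimetryConstants, Patient, Sex
from .retention import RetentionModel, retention_at

__all__ = [
    "BloodDoseResult",
    "MtaResult",
    "estimate_blood_volume",
    "blood_dose_coefficient",
    "total_blood_dose",
    "check_safety",
    "max_tolerated_activity",
    "evaluate_blood_dose",
]


@dataclass(frozen=True)
class BloodDoseResult:
    """Per-administration blood dosimetry outcome."""

    coefficient_mgy_per_mbq: float
    total_dose_gy: float
    blood_volume_ml: float
    tau_h: float
    within_conservative_limit: bool = False
    within_actual_limit: bool = False


@dataclass(frozen=True)
class MtaResult:
    """Maximum tolerated activity and the constraint that binds it."""

    a_max_blood_mbq: float
    a_max_benua_mbq: float
    a_max_mbq: float
    binding_constraint: Literal["blood", "benua_wb"]


def estimate_blood_volume(
    patient: Patient, constants: DosimetryConstants = DEFAULT_CONSTANTS
) -> float:
    """Blood volume in mL.

    Resolution order: an explicitly supplied ``blood_volume_ml`` is passed
    through; otherwise Nadler's sex-specific height/weight equations are used
    when height is available; otherwise a flat per-kg fallback
    (``constants.fallback_blood_ml_per_kg``, default 70 mL/kg).
    """
    if patient.blood_volume_ml is not None:
        return patient.blood_volume_ml
    if patient.height_cm is not None:
        h_m = patient.height_cm / 100.0
        if patient.sex is Sex.MALE:
            litres = 0.3669 * h_m**3 + 0.03219 * patient.weight_kg + 0.6041
        else:
            litres = 0.3561 * h_m**3 + 0.03308 * patient.weight_kg + 0.1833
        return litres * 1000.0
    return constants.fallback_blood_ml_per_kg * patient.weight_kg


def blood_dose_coefficient(
    weight_kg: float,
    blood_volume_ml: float,
    tau_h: float,
    constants: DosimetryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Blood absorbed dose per administered activity, mGy/MBq.

    ``tau_h`` may be 0 (no residence, zero dose); weight and blood volume
    must be strictly positive.
    """
    if not weight_kg > 0 or not blood_volume_ml > 0:
        raise ValueError("weight_kg and blood_volume_ml must be > 0")
    if tau_h < 0:
        raise ValueError(f"tau_h must be >= 0, got {tau_h!r}")
    return (
        constants.beta_self_factor / blood_volume_ml
        + constants.photon_factor / weight_kg ** (2.0 / 3.0)
    ) * tau_h


def total_blood_dose(coefficient_mgy_per_mbq: float, activity_mbq: float) -> float:
    """Total blood dose in Gy: D = d · A0 / 1000."""
    if coefficient_mgy_per_mbq < 0 or activity_mbq < 0:
        raise ValueError("coefficient and activity must be non-negative")
    return coefficient_mgy_per_mbq * activity_mbq / 1000.0


def check_safety(
    result: BloodDoseResult, constants: DosimetryConstants = DEFAULT_CONSTANTS
) -> BloodDoseResult:
    """Set the two safety flags on a dose result (inclusive comparisons).

    The conservative flag compares the estimated dose against the tightened
    estimated-dose ceiling (default 1.3 Gy, which already encodes the ~0.67
    estimated-to-actual ratio); the actual flag compares the same estimate
    against the 2 Gy blood limit directly.
    """
    return dataclasses.replace(
        result,
        within_conservative_limit=(
            result.total_dose_gy <= constants.conservative_estimated_limit_gy
        ),
        within_actual_limit=(result.total_dose_gy <= constants.actual_blood_limit_gy),
    )


def max_tolerated_activity(
    coefficient_mgy_per_mbq: float,
    model: RetentionModel,
    constants: DosimetryConstants = DEFAULT_CONSTANTS,
    limit_gy: float | None = None,
) -> MtaResult:
    """Largest administered activity satisfying the blood-dose and 48-h
    whole-body retention constraints.

    ``limit_gy`` defaults to the conservative estimated-dose ceiling.  The
    blood constraint gives A = limit·1000/d; the retention constraint gives
    A = 4.4 GBq / R(48 h).  The binding (smaller) constraint is named.
    """
    if limit_gy is None:
        limit_gy = constants.conservative_estimated_limit_gy
    if not coefficient_mgy_per_mbq > 0:
        raise ValueError(
            f"coefficient must be > 0, got {coefficient_mgy_per_mbq!r}"
        )
    if not limit_gy > 0:
        raise ValueError(f"limit_gy must be > 0, got {limit_gy!r}")
    a_blood = limit_gy * 1000.0 / coefficient_mgy_per_mbq
    a_benua = constants.benua_wb_48h_limit_mbq / retention_at(model, 48.0)
    if a_blood <= a_benua:
        return MtaResult(a_blood, a_benua, a_blood, "blood")
    return MtaResult(a_blood, a_benua, a_benua, "benua_wb")


def evaluate_blood_dose(
    patient: Patient,
    activity_mbq: float,
    model: RetentionModel,
    constants: DosimetryConstants = DEFAULT_CONSTANTS,
) -> BloodDoseResult:
    """Full per-administration dosimetry: BVL → coefficient → dose → flags."""
    bvl = estimate_blood_volume(patient, constants)
    d = blood_dose_coefficient(patient.weight_kg, bvl, model.tau_h, constants)
    total = total_blood_dose(d, activity_mbq)
    return check_safety(
        BloodDoseResult(
            coefficient_mgy_per_mbq=d,
            total_dose_gy=total,
            blood_volume_ml=bvl,
            tau_h=model.tau_h,
        ),
        constants,
    )
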