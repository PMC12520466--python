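"""Units, dosimetric constants and shared domain records.

All internal computation uses MBq, hours, kg, mL and mGy; conversion to
mCi / GBq / Gy happens only at I/O boundaries.  1 mCi = 37 MBq is exact by
definition of the curie.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "MBQ_PER_MCI",
    "Sex",
    "RiskStratum",
    "DutchCategory",
    "Preparation",
    "DosimetryConstants",
    "DEFAULT_CONSTANTS",
    "Patient",
    "Administration",
    "mci_to_mbq",
    "mbq_to_mci",
]

MBQ_PER_MCI = 37.0


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class RiskStratum(str, Enum):
    """Empirical risk tier driving the fixed-activity prescription."""

    ABLATION = "ablation"
    ADJUVANT = "adjuvant"
    THERAPY = "therapy"
    METASTATIC = "metastatic"


class DutchCategory(str, Enum):
    """Cap category for the 100 MBq/kg pediatric rule."""

    T3B_N1 = "t3b_n1"
    T4_M1 = "t4_m1"
    UNCAPPED = "uncapped"


class Preparation(str, Enum):
    RHTSH = "rhtsh"
    WITHDRAWAL = "withdrawal"


@dataclass(frozen=True)
class DosimetryConstants:
    """Physical and regulatory constants for I-131 blood dosimetry.

    The beta self-dose factor 15.12 mGy·mL/(MBq·h) equals 108 × 0.14: the
    whole-body beta coefficient scaled by the fraction of whole-body
    residence time attributable to blood (MIRD assumption).  The photon
    factor 0.0188 mGy·kg^(2/3)/(MBq·h) carries the body-size scaling of the
    penetrating-photon contribution.  The classical safety envelope limits
    the blood absorbed dose to 2 Gy while keeping whole-body retention at
    48 h under 4.4 GBq (and lung retention at 24 h under 3 GBq; no lung
    input is modelled here, the constant is informational).  Because the
    simple estimate runs about 0.67 × the full blood-sampling dosimetry, a
    conservative estimated-dose ceiling of 1.3 Gy stands in for the 2 Gy
    actual limit.

    Every field can be overridden through :meth:`from_mapping` /
    :meth:`from_file` so study thresholds are not hard-wired into
    operations.
    """

    mbq_per_mci: float = MBQ_PER_MCI
    beta_self_factor: float = 15.12  # mGy·mL/(MBq·h), = 108 × blood_fraction
    photon_factor: float = 0.0188  # mGy·kg^(2/3)/(MBq·h)
    blood_fraction: float = 0.14
    actual_blood_limit_gy: float = 2.0
    estimated_to_actual_ratio: float = 0.67
    conservative_estimated_limit_gy: float = 1.3
    benua_wb_48h_limit_mbq: float = 4440.0
    benua_lung_24h_limit_mbq: float = 2960.0
    discharge_threshold_usv_h: float = 30.0
    check_threshold_65h_usv_h: float = 10.0
    dutch_rate_mbq_per_kg: float = 100.0
    dutch_cap_t3bn1_mbq: float = 5550.0
    dutch_cap_t4m1_mbq: float = 7400.0
    adult_reference_weight_kg: float = 70.0
    fallback_blood_ml_per_kg: float = 70.0  # pediatric 75-80 selectable

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")
        if self.conservative_estimated_limit_gy > self.actual_blood_limit_gy:
            raise ValueError(
                "conservative estimated limit exceeds the actual blood limit"
            )
        expected_beta = 108.0 * self.blood_fraction
        if abs(self.beta_self_factor - expected_beta) > 1e-3 * expected_beta:
            raise ValueError(
                "beta_self_factor must equal 108 x blood_fraction "
                f"({expected_beta:.4g}), got {self.beta_self_factor!r}"
            )
        if not self.dutch_cap_t3bn1_mbq < self.dutch_cap_t4m1_mbq:
            raise ValueError("T3b/N1 cap must lie below the T4/M1 cap")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "DosimetryConstants":
        """Build constants from a mapping; absent fields keep their defaults."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown constant name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "DosimetryConstants":
        """Load overrides from a YAML or JSON file (YAML is a JSON superset)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ValueError(f"constants file {path} must contain a mapping")
        return cls.from_mapping(data)


DEFAULT_CONSTANTS = DosimetryConstants()


@dataclass(frozen=True)
class Patient:
    """Demographics and risk descriptors of one pediatric patient.

    ``blood_volume_ml`` may be supplied directly (e.g. from a clinical
    estimate); when absent it is derived downstream from height/weight.
    """

    id: str
    sex: Sex
    age_years: float
    weight_kg: float
    height_cm: float | None = None
    risk_stratum: RiskStratum = RiskStratum.THERAPY
    dutch_category: DutchCategory = DutchCategory.UNCAPPED
    prepubertal: bool = False
    blood_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise ValueError(f"weight_kg must be positive, got {self.weight_kg!r}")
        if self.height_cm is not None and not self.height_cm > 0:
            raise ValueError(f"height_cm must be positive, got {self.height_cm!r}")
        if self.blood_volume_ml is not None and not self.blood_volume_ml > 0:
            raise ValueError(
                f"blood_volume_ml must be positive, got {self.blood_volume_ml!r}"
            )
        if not 0 <= self.age_years <= 25:
            raise ValueError(
                f"age_years outside the pediatric range [0, 25]: {self.age_years!r}"
            )


@dataclass(frozen=True)
class Administration:
    """One course of orally administered I-131 activity."""

    patient_id: str
    activity_mbq: float
    course_index: int = 1
    preparation: Preparation = Preparation.RHTSH

    def __post_init__(self) -> None:
        if not self.activity_mbq > 0:
            raise ValueError(
                f"activity_mbq must be positive, got {self.activity_mbq!r}"
            )
        if self.course_index < 1:
            raise ValueError(f"course_index must be >= 1, got {self.course_index!r}")


def mci_to_mbq(activity_mci: float) -> float:
    """Convert millicuries to megabecquerels (exact: 1 mCi = 37 MBq)."""
    if activity_mci < 0:
        raise ValueError(f"activity must be non-negative, got {activity_mci!r}")
    return activity_mci * MBQ_PER_MCI


def mbq_to_mci(activity_mbq: float) -> float:
    """Convert megabecquerels to millicuries (exact inverse of mci_to_mbq)."""
    if activity_mbq < 0:
        raise ValueError(f"activity must be non-negative, got {activity_mbq!r}")
    return activity_mbq / MBQ_PER_MCI


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses, enums and numpy scalars for JSON output."""
    import numpy as np

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    return obj


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_jsonable(obj), indent=2) + "\n")
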