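"""Activity-prescription strategies and the AHASA constraint engine.

Three prescription rules are compared: the empirical risk-stratified tier
(fixed mCi per stratum), linear body-weight scaling of an adult reference
dose, and the 100 MBq/kg pediatric rule with category caps (5550 MBq for
T3b/N1 disease, 7400 MBq for T4/M1).  The AHASA ("as high as safe
administration") step then caps any proposed activity at the patient's
maximum tolerated activity; it never raises a proposal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core import (
    DEFAULT_CONSTANTS,
    DosimetryConstants,
    DutchCategory,
    RiskStratum,
    mci_to_mbq,
)
from .dosimetry import MtaResult

__all__ = [
    "EMPIRICAL_DOSE_MCI",
    "DoseRecommendation",
    "empirical_dose",
    "bw_based_dose",
    "dutch_dose",
    "ahasa_adjust",
]

# Single default per tier; ranged tiers (adjuvant 50-75, therapy 100-150,
# metastatic 150-200) collapse to the modal/low value actually prescribed.
EMPIRICAL_DOSE_MCI: Mapping[RiskStratum, float] = {
    RiskStratum.ABLATION: 30.0,
    RiskStratum.ADJUVANT: 50.0,
    RiskStratum.THERAPY: 150.0,
    RiskStratum.METASTATIC: 200.0,
}


@dataclass(frozen=True)
class DoseRecommendation:
    """A proposed activity and the cap (if any) that reduced it."""

    strategy: str
    raw_activity_mbq: float
    final_activity_mbq: float
    cap_applied: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.final_activity_mbq > 0:
            raise ValueError("final activity must be > 0")
        if self.final_activity_mbq > self.raw_activity_mbq:
            raise ValueError("final activity cannot exceed the raw proposal")
        reduced = self.final_activity_mbq < self.raw_activity_mbq
        if reduced != (self.cap_applied is not None):
            raise ValueError("cap_applied must be set iff the proposal was reduced")


def empirical_dose(
    risk_stratum: RiskStratum | str,
    table: Mapping[RiskStratum, float] | None = None,
) -> float:
    """Fixed empirical activity in mCi for a risk stratum.

    Deliberately a lookup table: the case-by-case multidisciplinary
    adjustment that surrounds these tiers in practice is not modelled.
    """
    stratum = RiskStratum(risk_stratum)
    table = EMPIRICAL_DOSE_MCI if table is None else table
    if stratum not in table:
        raise ValueError(f"no empirical dose configured for stratum {stratum!r}")
    return table[stratum]


def bw_based_dose(weight_kg: float, adult_dose_mci: float) -> float:
    """Body-weight scaled dose in mCi: weight / 70 kg × adult dose, uncapped."""
    if not weight_kg > 0 or not adult_dose_mci > 0:
        raise ValueError("weight_kg and adult_dose_mci must be > 0")
    return weight_kg / DEFAULT_CONSTANTS.adult_reference_weight_kg * adult_dose_mci


def dutch_dose(
    weight_kg: float,
    dutch_category: DutchCategory | str,
    constants: DosimetryConstants = DEFAULT_CONSTANTS,
) -> DoseRecommendation:
    """100 MBq/kg rule with category caps.

    The rule is scoped clinically to the prepubertal subgroup; this function
    computes it for any weight and leaves the scoping to the caller.
    """
    category = DutchCategory(dutch_category)
    if not weight_kg > 0:
        raise ValueError(f"weight_kg must be > 0, got {weight_kg!r}")
    raw = constants.dutch_rate_mbq_per_kg * weight_kg
    caps = {
        DutchCategory.T3B_N1: (constants.dutch_cap_t3bn1_mbq, "dutch_t3bn1"),
        DutchCategory.T4_M1: (constants.dutch_cap_t4m1_mbq, "dutch_t4m1"),
    }
    if category in caps:
        cap_mbq, cap_name = caps[category]
        if raw > cap_mbq:
            return DoseRecommendation("dutch", raw, cap_mbq, cap_applied=cap_name)
    return DoseRecommendation("dutch", raw, raw)


def ahasa_adjust(proposed_mbq: float, mta: MtaResult) -> DoseRecommendation:
    """Cap a proposed activity at the patient's MTA (never raise it)."""
    if not proposed_mbq > 0:
        raise ValueError(f"proposed_mbq must be > 0, got {proposed_mbq!r}")
    if proposed_mbq > mta.a_max_mbq:
        return DoseRecommendation(
            "ahasa_adjusted",
            proposed_mbq,
            mta.a_max_mbq,
            cap_applied=f"mta_{mta.binding_constraint}".replace("benua_wb", "benua"),
            notes="reduced to the maximum tolerated activity",
        )
    return DoseRecommendation("ahasa_adjusted", proposed_mbq, proposed_mbq)


def empirical_dose_mbq(
    risk_stratum: RiskStratum | str,
    table: Mapping[RiskStratum, float] | None = None,
) -> float:
    """Empirical tier converted to MBq (internal working unit)."""
    return mci_to_mbq(empirical_dose(risk_stratum, table))
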