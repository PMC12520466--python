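"""Seeded synthetic pediatric cohorts: patients, administrations, readings.

The generator emulates the data-generating situation the analysis assumes:
adolescent patients (ages 11-20, mean 16.6, SD 2.3, 65% female) with
weights rising with age inside 35-135 kg; mono-exponential whole-body
clearance with a patient-varying effective half-life (lognormal, median
15 h, geometric SD 1.3); and two timed exposure-rate readings at 1 m
(defaults 2 h and 67 h) computed as a body-attenuated point-source dose
rate (0.03 μSv/h per MBq at 1 m) times the retained fraction, with
multiplicative lognormal measurement noise (CV 0.10).

A per-patient truth table (true λ, half-life, τ) is emitted alongside so
parameter-recovery tests can compare fitted against generating kinetics.

:func:`reference_cohort` additionally provides a frozen 20-patient /
24-administration table whose *categorical* marginals (sex, puberty, nodal
status, dose distribution, course counts, preparation, outcomes) match a
published pediatric DTC case series; its ages, weights and kinetics are
synthetic fabrications and must not be mistaken for patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import mci_to_mbq
from .dosing import EMPIRICAL_DOSE_MCI, RiskStratum

__all__ = ["CohortConfig", "CohortTables", "generate_cohort", "reference_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic data-generating process.

    The same seed always yields a bit-identical cohort (NumPy PCG64
    generator, fixed draw order).
    """

    n_patients: int = 20
    seed: int = 0
    age_mean: float = 16.6  # years
    age_sd: float = 2.3
    age_range: tuple[float, float] = (11.0, 20.0)
    p_female: float = 0.65
    weight_range: tuple[float, float] = (35.0, 135.0)  # kg
    # weight-age coupling: weight = intercept + slope*age + N(0, sd), clipped
    weight_age_intercept_kg: float = 12.0
    weight_age_slope_kg_per_y: float = 3.4
    weight_noise_sd_kg: float = 18.0
    half_life_median_h: float = 15.0  # effective, lognormal across patients
    half_life_gsd: float = 1.3  # geometric SD
    reading_times_h: tuple[float, float] = (2.0, 67.0)
    dose_rate_constant_usv_h_per_mbq: float = 0.03  # at 1 m, body-attenuated
    reading_noise_cv: float = 0.10  # multiplicative lognormal
    p_rhtsh: float = 0.75
    prepubertal_age_cutoff_y: float = 14.0
    risk_mix: tuple[tuple[str, float], ...] = (
        ("therapy", 0.70),
        ("adjuvant", 0.20),
        ("metastatic", 0.10),
    )

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for lo, hi in (self.age_range, self.weight_range):
            if not lo < hi:
                raise ValueError(f"degenerate range ({lo}, {hi})")
        probs = [p for _, p in self.risk_mix]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("risk_mix probabilities must be >= 0 and sum to 1")
        if not 0 <= self.p_female <= 1 or not 0 <= self.p_rhtsh <= 1:
            raise ValueError("p_female and p_rhtsh must lie in [0, 1]")
        if self.reading_noise_cv < 0:
            raise ValueError("reading_noise_cv must be >= 0")
        if not self.half_life_median_h > 0 or not self.half_life_gsd >= 1:
            raise ValueError("half-life median must be > 0 and geometric SD >= 1")
        t1, t2 = self.reading_times_h
        if not 0 <= t1 < t2:
            raise ValueError("reading times must satisfy 0 <= t1 < t2")


@dataclass(frozen=True)
class CohortTables:
    """Generated cohort: four tidy tables plus the generating config."""

    patients: pd.DataFrame
    administrations: pd.DataFrame
    readings: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig = field(default=CohortConfig(), compare=False)


_DUTCH_BY_STRATUM = {
    "therapy": "t3b_n1",
    "adjuvant": "uncapped",
    "metastatic": "t4_m1",
    "ablation": "uncapped",
}


def generate_cohort(config: CohortConfig = CohortConfig()) -> CohortTables:
    """Draw one synthetic cohort.

    Each patient gets a single administration at the empirical tier of their
    risk stratum, true clearance kinetics, and one noisy exposure-rate
    reading per configured time.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    w_lo, w_hi = config.weight_range
    weight = np.clip(
        config.weight_age_intercept_kg
        + config.weight_age_slope_kg_per_y * age
        + rng.normal(0.0, config.weight_noise_sd_kg, n),
        w_lo,
        w_hi,
    )
    strata = rng.choice(
        [s for s, _ in config.risk_mix], size=n, p=[p for _, p in config.risk_mix]
    )
    half_life = config.half_life_median_h * np.exp(
        rng.normal(0.0, math.log(config.half_life_gsd), n)
    )
    lam = math.log(2.0) / half_life
    preparation = np.where(rng.random(n) < config.p_rhtsh, "rhtsh", "withdrawal")

    ids = [f"S{i + 1:03d}" for i in range(n)]
    patients = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "age_years": np.round(age, 2),
            "weight_kg": np.round(weight, 1),
            "height_cm": np.nan,
            "risk_stratum": strata,
            "dutch_category": [_DUTCH_BY_STRATUM[s] for s in strata],
            "prepubertal": age < config.prepubertal_age_cutoff_y,
            "blood_volume_ml": np.nan,
        }
    )
    activity = np.array(
        [mci_to_mbq(EMPIRICAL_DOSE_MCI[RiskStratum(s)]) for s in strata]
    )
    administrations = pd.DataFrame(
        {
            "patient_id": ids,
            "course_index": 1,
            "activity_mbq": activity,
            "preparation": preparation,
        }
    )

    sigma = math.sqrt(math.log(1.0 + config.reading_noise_cv**2))
    rows = []
    for t in config.reading_times_h:
        clean = config.dose_rate_constant_usv_h_per_mbq * activity * np.exp(-lam * t)
        # mean-one lognormal noise; sigma == 0 reproduces the clean rate
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, n)) if sigma > 0 else 1.0
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": ids,
                    "course_index": 1,
                    "time_h": t,
                    "rate_usv_h": clean * noise,
                }
            )
        )
    readings = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["patient_id", "time_h"], kind="stable")
        .reset_index(drop=True)
    )
    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "lambda_per_h": lam,
            "half_life_h": half_life,
            "tau_h": 1.0 / lam,
        }
    )
    return CohortTables(patients, administrations, readings, truth, config)


# Frozen fixture: one row per patient.  Columns: id, sex, age, weight,
# prepubertal, nodal status, dutch category, risk stratum, preparation,
# outcome, course doses (mCi).  Ages/weights are synthetic; only the
# categorical marginals are faithful to the published series:
# 13 F / 7 M; 4 prepubertal; N0/N1a/N1b = 6/4/10; preparation 15 rhTSH /
# 5 withdrawal; 24 administrations distributed 50/100/120/150/200 mCi =
# 1/6/2/14/1; 16 single / 4 double courses; outcomes 16/3/1
# remission/recurrence/persistent.
_FIXTURE_ROWS = [
    # persistent prepubertal girl, low weight, dose reduced 150 -> 120
    ("P01", "female", 11, 35.4, True, "N1b", "t3b_n1", "therapy", "rhtsh", "persistent", (120, 150)),
    ("P02", "male", 12, 38.0, True, "N0", "uncapped", "adjuvant", "rhtsh", "remission", (50,)),
    ("P03", "female", 13, 42.0, True, "N1a", "t3b_n1", "therapy", "rhtsh", "remission", (100,)),
    ("P04", "male", 13, 44.0, True, "N1b", "t3b_n1", "therapy", "withdrawal", "remission", (100,)),
    ("P05", "female", 15, 48.5, False, "N1b", "t3b_n1", "therapy", "rhtsh", "recurrence", (100, 150)),
    ("P06", "female", 15, 52.0, False, "N1b", "t3b_n1", "therapy", "rhtsh", "recurrence", (150, 150)),
    ("P07", "male", 16, 55.0, False, "N1a", "t3b_n1", "therapy", "withdrawal", "remission", (100,)),
    ("P08", "female", 16, 58.0, False, "N1b", "t3b_n1", "therapy", "rhtsh", "remission", (120,)),
    ("P09", "female", 17, 56.5, False, "N0", "uncapped", "therapy", "rhtsh", "remission", (100,)),
    ("P10", "male", 17, 63.0, False, "N1b", "t3b_n1", "therapy", "rhtsh", "remission", (150,)),
    ("P11", "female", 17, 60.0, False, "N1a", "t3b_n1", "therapy", "withdrawal", "remission", (150,)),
    ("P12", "female", 18, 66.0, False, "N1b", "t3b_n1", "therapy", "rhtsh", "remission", (150,)),
    # follicular carcinoma with lung metastases found on post-therapy imaging
    ("P13", "female", 18, 62.0, False, "N0", "t4_m1", "metastatic", "rhtsh", "recurrence", (150, 200)),
    ("P14", "male", 18, 72.0, False, "N1b", "t3b_n1", "therapy", "rhtsh", "remission", (150,)),
    # heaviest patient: BW-scaled dosing is clinically infeasible here
    ("P15", "female", 18, 135.0, False, "N1b", "t3b_n1", "therapy", "rhtsh", "remission", (150,)),
    ("P16", "female", 19, 68.0, False, "N1a", "t3b_n1", "therapy", "withdrawal", "remission", (150,)),
    ("P17", "male", 19, 75.0, False, "N0", "uncapped", "therapy", "rhtsh", "remission", (150,)),
    ("P18", "female", 19, 70.0, False, "N1b", "t3b_n1", "therapy", "rhtsh", "remission", (150,)),
    ("P19", "female", 20, 74.0, False, "N0", "uncapped", "therapy", "withdrawal", "remission", (100,)),
    ("P20", "male", 20, 82.0, False, "N0", "uncapped", "therapy", "rhtsh", "remission", (150,)),
]


def reference_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frozen 20-patient fixture mirroring the published series' categorical
    composition (synthetic ages, weights and patient identities).

    Returns ``(patients, administrations)``.  The patients table carries the
    extra columns ``nodal_status``, ``preparation`` and ``outcome`` used by
    fixture-level summaries.
    """
    patients = pd.DataFrame(
        [r[:10] for r in _FIXTURE_ROWS],
        columns=[
            "id",
            "sex",
            "age_years",
            "weight_kg",
            "prepubertal",
            "nodal_status",
            "dutch_category",
            "risk_stratum",
            "preparation",
            "outcome",
        ],
    )
    patients.insert(4, "height_cm", np.nan)
    patients["blood_volume_ml"] = np.nan
    admin_rows = [
        {
            "patient_id": r[0],
            "course_index": k + 1,
            "activity_mbq": mci_to_mbq(dose_mci),
            "activity_mci": float(dose_mci),
            "preparation": r[8],
        }
        for r in _FIXTURE_ROWS
        for k, dose_mci in enumerate(r[10])
    ]
    return patients, pd.DataFrame(admin_rows)
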