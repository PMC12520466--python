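"""Cohort-level statistics: strategy comparison, weight-dose regression,
safety audit, and the end-to-end study report.

The report pipeline per administration is: two-point retention fit → blood
volume → blood-dose coefficient → total blood dose → safety flags → maximum
tolerated activity → AHASA adjustment of the administered activity.  On top
of that, per-patient prescriptions under the empirical, body-weight and
100 MBq/kg strategies are tabulated and summarised, and the weight-versus-
coefficient association is quantified with ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_CONSTANTS,
    DosimetryConstants,
    DutchCategory,
    Patient,
    RiskStratum,
    Sex,
    mbq_to_mci,
    mci_to_mbq,
)
from .dosimetry import (
    BloodDoseResult,
    evaluate_blood_dose,
    max_tolerated_activity,
)
from .dosing import ahasa_adjust, bw_based_dose, dutch_dose, empirical_dose
from .retention import (
    ExposureReading,
    fit_two_point_retention,
    predict_exposure_rate,
    time_to_threshold,
)

__all__ = [
    "RegressionResult",
    "StrategySummary",
    "fit_weight_dose_regression",
    "plan_strategies",
    "summarize_strategies",
    "safety_audit",
    "run_study",
]

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS of blood-dose coefficient (mGy/MBq) on body weight (kg)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class StrategySummary:
    strategy: str
    mean_mci: float
    sd_mci: float  # sample SD (n-1)
    n: int


def fit_weight_dose_regression(
    pairs: Iterable[tuple[float, float]],
) -> RegressionResult:
    """OLS slope/intercept, R² and the two-sided slope t-test p-value.

    ``pairs`` is an iterable of (weight_kg, coefficient_mgy_per_mbq); a
    2-column array or DataFrame works too.  Requires n >= 3 and
    non-degenerate weights.  A constant response yields slope 0, R² 0, p 1.
    """
    arr = np.asarray(
        pairs.to_numpy() if isinstance(pairs, pd.DataFrame) else list(pairs),
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (weight, coefficient) 2-tuples")
    x, y = arr[:, 0], arr[:, 1]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("weights are all equal; slope is undefined")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, n)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
    )


_DEFAULT_STRATEGIES = ("empirical", "bw_based", "dutch")


def plan_strategies(
    patients: pd.DataFrame,
    strategies: Sequence[str] = _DEFAULT_STRATEGIES,
    adult_dose_mci: float = 150.0,
    constants: DosimetryConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Per-patient prescriptions under each strategy.

    Returns one row per (patient, strategy) with raw/final activity in MBq
    and mCi and the cap applied, if any.
    """
    rows = []
    for _, p in patients.iterrows():
        for strategy in strategies:
            if strategy == "empirical":
                mbq = mci_to_mbq(empirical_dose(p["risk_stratum"]))
                raw, final, cap = mbq, mbq, None
            elif strategy == "bw_based":
                mbq = mci_to_mbq(bw_based_dose(p["weight_kg"], adult_dose_mci))
                raw, final, cap = mbq, mbq, None
            elif strategy == "dutch":
                rec = dutch_dose(p["weight_kg"], p["dutch_category"], constants)
                raw, final, cap = rec.raw_activity_mbq, rec.final_activity_mbq, rec.cap_applied
            else:
                raise ValueError(f"unknown strategy {strategy!r}")
            rows.append(
                {
                    "patient_id": p["id"],
                    "strategy": strategy,
                    "raw_activity_mbq": raw,
                    "final_activity_mbq": final,
                    "final_activity_mci": mbq_to_mci(final),
                    "cap_applied": cap,
                }
            )
    return pd.DataFrame(rows)


def summarize_strategies(plans: pd.DataFrame) -> list[StrategySummary]:
    """Mean and sample SD (n−1) of the final activity in mCi per strategy."""
    if plans.empty or plans["patient_id"].nunique() < 2:
        raise ValueError("strategy summary needs at least 2 patients")
    out = []
    for strategy, grp in plans.groupby("strategy", sort=False):
        mci = grp["final_activity_mci"].to_numpy(dtype=float)
        out.append(
            StrategySummary(
                strategy=str(strategy),
                mean_mci=float(np.mean(mci)),
                sd_mci=float(np.std(mci, ddof=1)),
                n=len(mci),
            )
        )
    return out


def safety_audit(
    results: Sequence[BloodDoseResult] | pd.DataFrame,
    constants: DosimetryConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Exceedance counts over 1 Gy, the conservative limit and the actual
    limit, plus the extreme coefficient and total dose."""
    if isinstance(results, pd.DataFrame):
        totals = results["total_dose_gy"].to_numpy(dtype=float)
        coeffs = results["coefficient_mgy_per_mbq"].to_numpy(dtype=float)
    else:
        totals = np.array([r.total_dose_gy for r in results], dtype=float)
        coeffs = np.array([r.coefficient_mgy_per_mbq for r in results], dtype=float)
    if len(totals) == 0:
        raise ValueError("safety audit requires at least one dose result")
    n = len(totals)
    cons = constants.conservative_estimated_limit_gy
    act = constants.actual_blood_limit_gy
    return {
        "n": n,
        "n_over_1_gy": int(np.sum(totals > 1.0)),
        "n_over_conservative_limit": int(np.sum(totals > cons)),
        "n_over_actual_limit": int(np.sum(totals > act)),
        "fraction_over_1_gy": float(np.mean(totals > 1.0)),
        "max_coefficient_mgy_per_mbq": float(np.max(coeffs)),
        "min_coefficient_mgy_per_mbq": float(np.min(coeffs)),
        "max_total_dose_gy": float(np.max(totals)),
    }


def _patient_from_row(row: pd.Series) -> Patient:
    def opt(name: str) -> float | None:
        v = row.get(name)
        return None if v is None or pd.isna(v) else float(v)

    return Patient(
        id=str(row["id"]),
        sex=Sex(row["sex"]),
        age_years=float(row["age_years"]),
        weight_kg=float(row["weight_kg"]),
        height_cm=opt("height_cm"),
        risk_stratum=RiskStratum(row["risk_stratum"]),
        dutch_category=DutchCategory(row["dutch_category"]),
        prepubertal=bool(row.get("prepubertal", False)),
        blood_volume_ml=opt("blood_volume_ml"),
    )


def run_study(
    patients: pd.DataFrame,
    administrations: pd.DataFrame,
    readings: pd.DataFrame,
    constants: DosimetryConstants = DEFAULT_CONSTANTS,
    adult_dose_mci: float = 150.0,
    limit_gy: float | None = None,
    rhtsh_only: bool = False,
) -> dict:
    """Run the full dosimetry and planning pipeline on tabular inputs.

    ``readings`` must contain exactly two rows per administration
    (``patient_id``, ``course_index``, ``time_h``, ``rate_usv_h``); missing
    or surplus readings raise an itemised error.  With ``rhtsh_only``,
    dosimetry and the regression are restricted to rhTSH-prepared
    administrations (stimulated and withdrawal kinetics differ, so mixing
    them biases per-MBq dose estimates).

    Returns a JSON-serialisable report dict; deterministic given inputs.
    """
    if limit_gy is None:
        limit_gy = constants.conservative_estimated_limit_gy
    pat_by_id = {str(r["id"]): r for _, r in patients.iterrows()}

    admins = administrations
    if rhtsh_only:
        admins = admins[admins["preparation"] == "rhtsh"]
        if admins.empty:
            raise ValueError("no rhTSH-prepared administrations to analyse")

    grouped = readings.groupby(["patient_id", "course_index"])
    missing, rows = [], []
    for _, adm in admins.iterrows():
        key = (adm["patient_id"], adm["course_index"])
        try:
            grp = grouped.get_group(key)
        except KeyError:
            grp = pd.DataFrame()
        if len(grp) != 2:
            missing.append(f"{key[0]}/course{key[1]} ({len(grp)} readings)")
            continue
        grp = grp.sort_values("time_h")
        model = fit_two_point_retention(
            ExposureReading(float(grp.iloc[0]["time_h"]), float(grp.iloc[0]["rate_usv_h"])),
            ExposureReading(float(grp.iloc[1]["time_h"]), float(grp.iloc[1]["rate_usv_h"])),
        )
        patient = _patient_from_row(pat_by_id[str(adm["patient_id"])])
        activity = float(adm["activity_mbq"])
        dose = evaluate_blood_dose(patient, activity, model, constants)
        mta = max_tolerated_activity(
            dose.coefficient_mgy_per_mbq, model, constants, limit_gy
        )
        adj = ahasa_adjust(activity, mta)
        rows.append(
            {
                "patient_id": patient.id,
                "course_index": int(adm["course_index"]),
                "activity_mbq": activity,
                "weight_kg": patient.weight_kg,
                "tau_h": model.tau_h,
                "lambda_eff_per_h": model.lambda_eff_per_h,
                "bvl_ml": dose.blood_volume_ml,
                "coefficient_mgy_per_mbq": dose.coefficient_mgy_per_mbq,
                "total_dose_gy": dose.total_dose_gy,
                "within_conservative_limit": dose.within_conservative_limit,
                "within_actual_limit": dose.within_actual_limit,
                "a_max_mbq": mta.a_max_mbq,
                "binding_constraint": mta.binding_constraint,
                "ahasa_activity_mbq": adj.final_activity_mbq,
                "ahasa_cap_applied": adj.cap_applied,
                "discharge_time_h": time_to_threshold(
                    model, constants.discharge_threshold_usv_h
                ),
                "rate_at_65h_usv_h": predict_exposure_rate(model, 65.0),
            }
        )
    if missing:
        raise ValueError(
            "administrations without exactly two readings: " + ", ".join(missing)
        )
    dosimetry = pd.DataFrame(rows)

    included_ids = set(dosimetry["patient_id"])
    pat_subset = patients[patients["id"].astype(str).isin(included_ids)]
    plans = plan_strategies(pat_subset, adult_dose_mci=adult_dose_mci, constants=constants)
    summaries = summarize_strategies(plans)

    # Figure-style per-patient association: first analysed course per patient
    per_patient = (
        dosimetry.sort_values(["patient_id", "course_index"])
        .groupby("patient_id", as_index=False)
        .first()
    )
    regression = fit_weight_dose_regression(
        per_patient[["weight_kg", "coefficient_mgy_per_mbq"]]
    )
    audit = safety_audit(dosimetry, constants)
    audit["fraction_below_10usv_at_65h"] = float(
        np.mean(dosimetry["rate_at_65h_usv_h"] < constants.check_threshold_65h_usv_h)
    )

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "settings": {
            "limit_gy": limit_gy,
            "adult_dose_mci": adult_dose_mci,
            "rhtsh_only": rhtsh_only,
        },
        "n_patients": int(per_patient.shape[0]),
        "n_administrations": int(dosimetry.shape[0]),
        "dosimetry": dosimetry.to_dict(orient="records"),
        "strategy_plans": plans.to_dict(orient="records"),
        "strategy_summaries": [s.__dict__ for s in summaries],
        "regression_weight_vs_coefficient": regression.__dict__,
        "safety_audit": audit,
    }
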