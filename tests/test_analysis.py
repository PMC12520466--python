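import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raidose.analysis import (
    fit_weight_dose_regression,
    plan_strategies,
    run_study,
    safety_audit,
    summarize_strategies,
)
from raidose.cohort import CohortConfig, generate_cohort, reference_cohort
from raidose.dosimetry import BloodDoseResult


def _ols_oracle(x, y):
    """Independent closed-form OLS: slope, intercept, R², two-sided slope p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    dx, dy = x - x.mean(), y - y.mean()
    slope = (dx @ dy) / (dx @ dx)
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    ss_res, ss_tot = resid @ resid, dy @ dy
    r2 = 1 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 2) / (dx @ dx))
    p = 2 * stats.t.sf(abs(slope / se), n - 2)
    return slope, intercept, r2, p


class TestRegression:
    X = [1.0, 2.0, 3.0, 4.0, 5.0]
    Y = [2.0, 1.9, 1.7, 1.8, 1.5]

    def test_against_closed_form_oracle(self):
        res = fit_weight_dose_regression(zip(self.X, self.Y))
        slope, intercept, r2, p = _ols_oracle(self.X, self.Y)
        # hand values: slope = -0.11, intercept = 2.11, R² = 1 - 0.027/0.148
        assert slope == pytest.approx(-0.11, rel=1e-12)
        assert r2 == pytest.approx(1 - 0.027 / 0.148, rel=1e-9)
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)
        assert res.r_squared == pytest.approx(r2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)
        assert res.n == 5

    def test_collinear_points_exact_fit(self):
        res = fit_weight_dose_regression([(w, 0.2 - 0.001 * w) for w in (40, 60, 80, 100)])
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(-0.001, rel=1e-12)
        assert res.p_value < 1e-6

    def test_constant_response(self):
        res = fit_weight_dose_regression([(40, 0.1), (60, 0.1), (80, 0.1)])
        assert res.slope == 0.0
        assert res.r_squared == 0.0
        assert res.p_value == 1.0

    def test_r_squared_is_squared_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(35, 135, 30)
        y = 0.2 - 0.001 * x + rng.normal(0, 0.02, 30)
        res = fit_weight_dose_regression(zip(x, y))
        assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-12)

    def test_permutation_invariance(self):
        pairs = list(zip(self.X, self.Y))
        res1 = fit_weight_dose_regression(pairs)
        res2 = fit_weight_dose_regression(pairs[::-1])
        assert res1 == res2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_weight_dose_regression([(1, 2), (2, 3)])
        with pytest.raises(ValueError):
            fit_weight_dose_regression([(5, 1), (5, 2), (5, 3)])


class TestStrategySummaries:
    def test_hand_arithmetic(self):
        plans = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "strategy": "empirical",
                "final_activity_mci": [100.0, 150.0, 200.0],
            }
        )
        (s,) = summarize_strategies(plans)
        assert s.mean_mci == pytest.approx(150.0)
        assert s.sd_mci == pytest.approx(50.0)  # sample SD, n-1
        assert s.n == 3

    def test_constant_doses_zero_sd(self):
        plans = pd.DataFrame(
            {"patient_id": ["a", "b"], "strategy": "dutch", "final_activity_mci": [100.0, 100.0]}
        )
        assert summarize_strategies(plans)[0].sd_mci == 0.0

    def test_single_patient_rejected(self):
        plans = pd.DataFrame(
            {"patient_id": ["a"], "strategy": "dutch", "final_activity_mci": [100.0]}
        )
        with pytest.raises(ValueError):
            summarize_strategies(plans)

    def test_dutch_underdoses_low_rate_cohort(self):
        """When every patient's 100 MBq/kg dose sits below their empirical
        tier, the strategy mean must too."""
        patients, _ = reference_cohort()
        light = patients[patients["weight_kg"] < 55].copy()  # 100·w < 5550 for all
        plans = plan_strategies(light)
        means = {s.strategy: s.mean_mci for s in summarize_strategies(plans)}
        assert means["dutch"] < means["empirical"]

    def test_plan_strategies_columns_and_caps(self):
        patients, _ = reference_cohort()
        plans = plan_strategies(patients)
        assert set(plans["strategy"]) == {"empirical", "bw_based", "dutch"}
        assert len(plans) == 3 * len(patients)
        dutch = plans[plans["strategy"] == "dutch"]
        capped = dutch[dutch["cap_applied"].notna()]
        assert (capped["final_activity_mbq"] < capped["raw_activity_mbq"]).all()


class TestSafetyAudit:
    def _res(self, total, coeff=0.1):
        return BloodDoseResult(coeff, total, 4200.0, 21.7)

    def test_no_exceedance(self):
        audit = safety_audit([self._res(0.5), self._res(0.9)])
        assert audit["n_over_1_gy"] == 0
        assert audit["max_total_dose_gy"] == 0.9

    def test_single_exceedance_of_1gy_only(self):
        audit = safety_audit([self._res(1.05, 0.19), self._res(0.6, 0.06)])
        assert audit["n_over_1_gy"] == 1
        assert audit["n_over_conservative_limit"] == 0
        assert audit["n_over_actual_limit"] == 0
        assert audit["max_coefficient_mgy_per_mbq"] == 0.19
        assert audit["min_coefficient_mgy_per_mbq"] == 0.06

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            safety_audit([])


class TestRunStudy:
    def test_deterministic_report(self, small_cohort):
        r1 = run_study(small_cohort.patients, small_cohort.administrations, small_cohort.readings)
        r2 = run_study(small_cohort.patients, small_cohort.administrations, small_cohort.readings)
        assert r1 == r2
        assert r1["n_patients"] == 20
        assert {s["strategy"] for s in r1["strategy_summaries"]} == {
            "empirical", "bw_based", "dutch"
        }

    def test_noise_degrades_regression_fit(self):
        """Measurement noise on the readings lowers the average R² of the
        weight-coefficient regression relative to noiseless runs on the
        same underlying cohorts."""

        def mean_r2(cv):
            r2 = []
            for seed in range(9, 29):
                t = generate_cohort(
                    CohortConfig(n_patients=40, seed=seed, reading_noise_cv=cv)
                )
                rep = run_study(t.patients, t.administrations, t.readings)
                r2.append(rep["regression_weight_vs_coefficient"]["r_squared"])
            return np.mean(r2)

        assert mean_r2(0.0) > mean_r2(0.10)

    def test_missing_readings_itemised(self, small_cohort):
        readings = small_cohort.readings.iloc[:-1]  # drop one reading
        with pytest.raises(ValueError, match="S020"):
            run_study(small_cohort.patients, small_cohort.administrations, readings)

    def test_rhtsh_only_restricts_rows(self, small_cohort):
        full = run_study(small_cohort.patients, small_cohort.administrations, small_cohort.readings)
        sub = run_study(
            small_cohort.patients,
            small_cohort.administrations,
            small_cohort.readings,
            rhtsh_only=True,
        )
        n_rhtsh = (small_cohort.administrations["preparation"] == "rhtsh").sum()
        assert sub["n_administrations"] == n_rhtsh < full["n_administrations"]

    def test_rhtsh_only_with_no_rhtsh_rows_rejected(self, small_cohort):
        admins = small_cohort.administrations.assign(preparation="withdrawal")
        with pytest.raises(ValueError, match="rhTSH"):
            run_study(small_cohort.patients, admins, small_cohort.readings, rhtsh_only=True)

    def test_fixture_with_synthetic_kinetics_stays_under_2gy(self):
        """Running the frozen fixture with generated kinetics keeps every
        administration within the actual blood limit."""
        patients, administrations = reference_cohort()
        rng = np.random.default_rng(2024)
        rows = []
        for _, adm in administrations.iterrows():
            lam = np.log(2) / (15.0 * np.exp(rng.normal(0, np.log(1.3))))
            a0 = adm["activity_mbq"]
            for t in (2.0, 67.0):
                rows.append(
                    {
                        "patient_id": adm["patient_id"],
                        "course_index": adm["course_index"],
                        "time_h": t,
                        "rate_usv_h": 0.03 * a0 * np.exp(-lam * t),
                    }
                )
        report = run_study(patients, administrations, pd.DataFrame(rows))
        assert report["n_administrations"] == 24
        assert report["safety_audit"]["n_over_actual_limit"] == 0
        assert report["regression_weight_vs_coefficient"]["slope"] < 0
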