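# raidose

Blood dosimetry and activity planning for radioactive-iodine (I-131)
therapy in pediatric differentiated thyroid cancer (DTC).

After total thyroidectomy, the administered I-131 activity must balance
efficacy against the radiation absorbed dose to blood — the accepted proxy
for red-marrow exposure. The classical safety envelope limits the blood
dose to 2 Gy while keeping whole-body retention at 48 h under 4.4 GBq.
Full blood-sampling dosimetry takes days and is rarely practised, so this
package implements a simple two-measurement estimate suitable for routine
use: from two timed exposure-rate readings at 1 m, it derives the
whole-body residence time, the blood absorbed dose per administered
activity, each patient's maximum tolerated activity (MTA), and a dose
recommendation under the AHASA ("as high as safe administration")
principle. It is aimed at medical physicists and nuclear-medicine
researchers comparing pediatric prescription strategies.

## Model

Whole-body retention is mono-exponential, R(t) = exp(−λt), with λ fitted
from readings (t₁, X₁) and (t₂, X₂):

    λ = ln(X₁/X₂) / (t₂ − t₁),    τ = 1/λ = −t / ln R(t)

The blood absorbed dose coefficient combines a beta self-dose term and a
photon term:

    d = D_blood/A₀ = (15.12/BVL + 0.0188/wt^(2/3)) · τ    [mGy/MBq]

with BVL the blood volume (mL), wt the weight (kg) and τ in hours. The
15.12 factor is the whole-body beta coefficient scaled by the 14% of
whole-body residence time attributable to blood (MIRD assumption). Because
this simplified estimate runs about 0.67× full blood-sampling dosimetry,
an estimated-dose ceiling of 1.3 Gy stands in for the 2 Gy actual limit.
The MTA is then

    A_max = min( limit·1000 / d ,  4440 MBq / R(48 h) )

and the AHASA step caps any proposed activity at A_max (it never raises
one). Three prescription strategies are provided for comparison: empirical
risk-stratified tiers (30/50/150/200 mCi), body-weight scaling
(wt/70 kg × adult dose), and the 100 MBq/kg pediatric rule with 5550/7400
MBq category caps. A seeded synthetic-cohort generator and a frozen
20-patient reference fixture (categorical marginals from a published
pediatric DTC series; ages, weights and kinetics fabricated) support
testing and power analysis.

## Worked example

```python
from raidose import *

# Two readings at 1 m: 200 uSv/h at 2 h, 10 uSv/h at 67 h
model = fit_two_point_retention(ExposureReading(2.0, 200.0),
                                ExposureReading(67.0, 10.0))

patient = Patient(id="P01", sex=Sex.FEMALE, age_years=11, weight_kg=35.4,
                  risk_stratum=RiskStratum.THERAPY,
                  dutch_category=DutchCategory.T3B_N1, prepubertal=True)

bvl = estimate_blood_volume(patient)                      # 70 mL/kg fallback
d = blood_dose_coefficient(patient.weight_kg, bvl, model.tau_h)
proposed = mci_to_mbq(empirical_dose(patient.risk_stratum))
mta = max_tolerated_activity(d, model)                    # 1.3 Gy ceiling
rec = ahasa_adjust(proposed, mta)
```

This prints, step by step:

```
lambda_eff = 0.04609 /h   tau = 21.70 h
BVL = 2478 mL   d = 0.1702 mGy/MBq
proposed 5550 MBq -> blood dose 0.945 Gy
MTA = 7637 MBq (binding: blood)
AHASA: 5550 MBq (150 mCi), cap = None
discharge (<30 uSv/h) at t = 43.2 h
```

Read: the 11-year-old, 35.4 kg patient clears with an effective half-life
of 15 h (τ = 21.7 h). Her low blood volume puts the coefficient at
0.17 mGy/MBq — near the top of the clinically observed 0.06–0.19 band —
but the 150 mCi (5550 MBq) empirical tier still delivers only 0.945 Gy,
inside the 1.3 Gy conservative ceiling, so AHASA leaves the prescription
uncapped; the blood constraint (not 48-h retention) is the one that would
bind first, at 7637 MBq. Predicted discharge (below 30 μSv/h at 1 m) comes
at 43 h.

The same pipeline runs from the shell:

```sh
raidose simulate --n 20 --seed 42 --out cohort/
raidose plan --patients cohort/patients.csv --strategy dutch --out plan.csv
raidose report --patients cohort/patients.csv \
    --administrations cohort/administrations.csv \
    --readings cohort/readings.csv --rhtsh-only --out report.json
```

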