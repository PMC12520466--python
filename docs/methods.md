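# Methods

## Retention model

Whole-body I-131 retention is modelled as a single exponential,
R(t) = exp(−λt), normalised to R(0) = 1 at administration and extrapolated
back to t = 0 (required by the 48-h retention check). The effective decay
constant λ combines physical decay and biological clearance and is fitted
from exactly two timed exposure-rate readings at 1 m:
λ = ln(X₁/X₂)/(t₂ − t₁). The exposure rate is treated as proportional to
retained activity, so the proportionality constant cancels in the ratio.
The customary reading times are 2 h and 67 h (a 65-h window spanning the
typical 72-h radiation-ward stay), but the fitter accepts any two distinct
times; 2/67 h are documented defaults only, never hard-coded.

Assumptions and their limits:

- Mono-exponential clearance ignores the early fast phase (pre-void renal
  clearance) and any multi-compartment kinetics. No multi-point or
  bi-exponential fitting is offered; with only two readings the model is
  exactly identified and least squares would be vacuous.
- Readings are assumed background-corrected upstream; no ambient dose-rate
  subtraction is applied.
- Paired readings with a non-decreasing rate are rejected as non-physical
  rather than silently clamped.

## Blood absorbed dose

The per-activity blood dose coefficient is

    d = (15.12 / BVL + 0.0188 / wt^(2/3)) · τ     [mGy/MBq]

with BVL in mL, wt in kg, τ = 1/λ in hours. The beta self-dose factor
15.12 mGy·mL/(MBq·h) is the whole-body beta coefficient (108) scaled by
the 14% of whole-body residence time attributable to blood; the photon
factor 0.0188 mGy·kg^(2/3)/(MBq·h) carries the body-size scaling of the
penetrating contribution. The total dose is D = d·A₀/1000 Gy.

Blood volume resolution order: an explicit per-patient value wins; with a
height on record, Nadler's sex-specific equations are used
(male 0.3669·H[m]³ + 0.03219·W + 0.6041 L; female 0.3561·H³ + 0.03308·W +
0.1833 L); otherwise a flat 70 mL/kg fallback applies. The fallback rate
is configurable (pediatric practice sometimes uses 75–80 mL/kg), and the
choice of method is deliberately isolated in one function because the
per-kg rule makes d strictly decreasing in weight — the mechanism behind
the negative weight-versus-dose association the analysis module
quantifies. Nadler's equations were derived in adults; applying them to
younger children is an extrapolation, which is one reason the per-kg
fallback remains the default when height is absent rather than a
synthesised height.

## Safety limits and MTA

Two inclusive flags are attached to every dose estimate: the estimated
dose against the 1.3 Gy conservative ceiling, and the same estimate
against the 2 Gy actual blood limit. The 1.3 Gy figure encodes the ~0.67
ratio of this simplified estimate to full blood-sampling dosimetry
(2 × 0.67 ≈ 1.3); the ratio is applied once, as a tightened limit, never
as a multiplicative correction of d. The maximum tolerated activity is

    A_max = min( limit·1000/d ,  4440 MBq / R(48 h) )

with the binding constraint reported. The 24-h lung-retention limit
(2960 MBq) is kept as a constant for completeness but drives no operation:
the pipeline has no lung-uptake input. The AHASA adjustment caps a
proposed activity at A_max and never escalates a proposal, mirroring
clinical practice where low-weight patients had tiers reduced but nobody
was dosed above their tier.

Dose outputs are not rounded to capsule increments; any rounding policy is
left to the caller.

## Prescription strategies

- **Empirical**: fixed mCi per risk stratum — ablation 30, adjuvant 50,
  therapy 150, metastatic 200. Published tiers are ranges (adjuvant 50–75,
  therapy 100–150, metastatic 150–200); the defaults take the modal/low
  values actually prescribed and the table is overridable. The
  multidisciplinary, case-by-case judgment that surrounds these tiers in
  practice is explicitly not modelled: the operation is a lookup table.
- **Body-weight**: wt/70 kg × adult reference dose, uncapped — included
  because its wide spread (0.5–1.9× across 35–135 kg) is exactly the
  problem the comparison exposes.
- **100 MBq/kg rule**: raw = 100·wt MBq, capped at 5550 MBq (T3b/N1) or
  7400 MBq (T4/M1). The rule is scoped clinically to prepubertal patients;
  the function computes it for any weight and leaves scoping to the
  caller. A dose exactly at the cap is not flagged as capped (a cap is
  recorded only when it reduces the proposal).

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| age | truncated normal, mean 16.6 y, SD 2.3, range 11–20 | adolescent DTC demographics |
| sex | 65% female | observed series composition |
| weight | 12 + 3.4·age + N(0, 18) kg, clipped to 35–135 | couples weight to age so prepubertal patients occupy the low-weight tail; spread wide enough that weight, not kinetic noise, dominates the dose coefficient |
| risk mix | therapy 0.70 / adjuvant 0.20 / metastatic 0.10 | typical post-thyroidectomy case mix |
| effective half-life | lognormal, median 15 h, geometric SD 1.3 | athyreotic whole-body clearance of I-131 under stimulation; right-skewed across patients |
| dose-rate constant | 0.03 μSv/h per MBq at 1 m | I-131 point-source constant (~0.052 μSv·m²/(MBq·h)) attenuated by the body |
| reading noise | multiplicative lognormal, CV 0.10, mean 1 | survey-meter repeatability plus positioning error |
| reading times | 2 h and 67 h | ward admission and pre-discharge checks |
| preparation | 75% rhTSH | observed series composition |

Each patient receives one administration at the empirical tier of their
stratum. A truth table (true λ, half-life, τ) is emitted so recovery tests
can compare fitted against generating kinetics; with noise CV set to 0 the
fit recovers λ to numerical precision. The same seed yields a bit-identical
cohort (NumPy PCG64, fixed draw order).

What the generator does **not** emulate — and hence what green tests do
not certify about real data: altered kinetics of second courses or of
withdrawal versus rhTSH preparation, tumor-burden and renal-function
effects on clearance, correlated measurement drift, missing or mistimed
readings, and heights (generated patients use the per-kg blood-volume
fallback).

The frozen 20-patient reference fixture reproduces only the *categorical*
marginals of a published pediatric DTC case series — 13 F / 7 M, 4
prepubertal, N0/N1a/N1b = 6/4/10, 15 rhTSH / 5 withdrawal, 24
administrations distributed 50/100/120/150/200 mCi = 1/6/2/14/1, 16
single / 4 double courses, outcomes 16/3/1 remission/recurrence/persistent.
Its ages, weights and identities are fabricated and are labelled as such;
it must not be mistaken for patient data. The four two-course patients are
identified with the three recurrent plus one persistent case so the course
counts, dose distribution and outcome counts hold simultaneously.

## Analysis

The weight-versus-coefficient association is ordinary least squares
(scipy's linregress behind the module surface), reporting slope,
intercept, R² and the two-sided slope t-test p-value with n − 2 degrees of
freedom; a constant response returns slope 0, R² 0, p 1, and degenerate
weights or n < 3 raise. Strategy summaries use the sample SD (n − 1).
Where readings are noisy, measurement error lands in the response (the
fitted coefficient), so R² degrades with noise but the slope stays
centred; the regression is descriptive, no errors-in-variables correction
is attempted.

`run_study` chains, per administration: two-point fit → blood volume →
coefficient → total dose → safety flags → MTA → AHASA adjustment →
discharge-time and 65-h rate predictions; then per-patient strategy plans,
strategy summaries, the weight regression (first analysed course per
patient) and a safety audit, into one JSON-serialisable report
(schema_version 1). The `rhtsh_only` switch restricts dosimetry to
rhTSH-prepared administrations, since stimulated and withdrawal kinetics
differ and mixing them biases per-MBq estimates. An administration without
exactly two readings aborts the run with an itemised error rather than a
partial report.

## Numerical choices and problem sizes

- All internal computation in MBq, hours, kg, mL, mGy; 1 mCi = 37 MBq is
  exact. Conversions to mCi/GBq/Gy happen only at I/O boundaries.
- Safety comparisons are inclusive (≤); ties in the MTA minimum are
  attributed to the blood constraint.
- τ = 0 is admitted in the coefficient (zero dose) as the closed limit of
  the no-residence case.
- Statistical checks run at: one n = 200 cohort for the coefficient-band
  coverage; 500 replicates of n = 15 for regression power; a 39-point λ
  grid for noiseless recovery; 1000 random cases for AHASA constraint
  closure. These sizes give stable estimates (power fluctuates by ~±3
  points across seeds) while keeping the whole suite fast.

## Known limitations

- Two readings exactly; no robustness to a bad reading and no uncertainty
  on λ or d is propagated.
- The 0.67 estimated-to-actual ratio is a fixed scalar from external
  calibration, not re-estimated here; no direct validation against full
  blood-sampling dosimetry is performed.
- The empirical-tier lookup ignores the clinical judgment layer; the
  body-weight strategy is included for comparison, not recommendation.
- Blood-volume estimation in children is the dominant systematic
  uncertainty in d and is configurable for exactly that reason.
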