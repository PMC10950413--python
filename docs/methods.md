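# Methods

## Disposition model

Serum magnesium is modelled as an additive endogenous baseline plus the
drug-attributable concentration of a mammillary two-compartment system with
first-order elimination from the central compartment:

    dA1/dt = in(t) − (k10 + k12)·A1 + k21·A2
    dA2/dt = k12·A1 − k21·A2
    C(t)   = baseline + A1(t)/V1

with micro constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 and hybrid rate
constants α > β > 0, the roots of s² + (k10+k12+k21)s + k10·k21 = 0. The unit
constant-infusion response is the biexponential

    C_u(t) = (1/V1)·[(A/α)(1 − e^{−αt}) + (B/β)(1 − e^{−βt})],
    A = (α − k21)/(α − β),   B = (k21 − β)/(α − β),

whose t→∞ limit is 1/CL. Because the system is linear and time-invariant, an
arbitrary dosing history is evaluated by superposition: every maintenance
rate *increment* (changes and stops are negative increments) contributes a
shifted copy of C_u, and a bolus is a short zero-order infusion of
configurable duration (default 20 min — the administration time is rarely
charted; an instantaneous mode, `D/V1·(A e^{−αt} + B e^{−βt})`, is the
duration→0 limit). This closed form is exact; the test suite holds it to
< 1e−6 mmol/L of an independent DOP853 integration of the ODE system across
random parameters and schedules.

Assumptions worth stating: the endogenous baseline (default 0.74 mmol/L,
a typical pre-treatment serum magnesium in preeclampsia) is an additive
constant with no turnover; disposition is linear (no saturable renal
reabsorption); parameters are constant within a case (no delivery-related
clearance change).

## Parameters and individualization

| parameter | unit | default | meaning |
|---|---|---|---|
| CL | L/h | 4.0 | elimination clearance |
| V1 | L | 20.0 | central volume |
| Q | L/h | 2.0 | intercompartmental clearance |
| V2 | L | 30.0 | peripheral volume |
| baseline | mmol/L | 0.74 | endogenous serum magnesium |
| dose_to_amount | mmol/g | 4.06 | elemental Mg per labelled gram (MgSO4·7H2O) |

The typical values are an explicit **placeholder** parameterisation chosen to
give physiologically plausible kinetics (terminal half-life ≈ 17 h, 1 g/h
steady state ≈ 1.76 mmol/L); published population estimates should be
transcribed into the config before clinical-mimicking use. The salt form is
config-exposed through `dose_to_amount` because labelled doses are reported
in grams of salt, not millimoles of magnesium.

Individualization multiplies the typical values by covariate functions
anchored at reference covariates (70 kg, 60 µmol/L), where they equal 1
exactly: allometric body weight on CL and Q (exponent 0.75), proportional
weight on V1/V2, and inverse serum creatinine on CL. Magnesium is renally
eliminated, so low creatinine (high filtration) raises clearance and lowers
attainable concentrations; high weight raises volumes and absolute clearance.
Both power and linear forms are supported per parameter.

## Synthetic cohort generator

The generator emulates a guideline-treated cohort so that every downstream
stage is exercised without patient-level data. What it reproduces:

* **Demographics** — weight, creatinine, gestational age and treatment
  duration are drawn from two-piece log-normal marginals solved to hit the
  cohort summary quartiles exactly (weight 73/84/95 kg, creatinine
  51/57/69 µmol/L, duration 23.7/29.6/46.0 h); the two-piece form is needed
  because the printed quartiles are right-skewed beyond a single log-normal.
  Weight and creatinine are independent by default, with an optional
  Gaussian-copula correlation. Durations are floored at 6 h (shorter courses
  cannot yield the two measurements eligibility requires) and treatment is
  capped at 60 h.
* **Protocol closed loop** — 4 g/20 min bolus, 1 g/h maintenance, a check
  1 h after start and after every change; if the *measured* value is below
  2.0 mmol/L the rate increases by 0.25 g/h. Decisions are driven by the
  error-corrupted measurement, as on the ward, so measurement noise feeds
  back into dosing. The rate is capped at 2.0 g/h: the printed rule alone
  would ratchet indefinitely while concentrations lag the target, which
  contradicts observed practice (rates plateau once the early titration
  window passes) and would manufacture toxic steady states; the cap is the
  simulator's rendering of that plateau. Scheduled samples at 4, 8, 12, 18,
  24 h and every 12 h thereafter complement the titration checks.
* **Measurement error** — proportional CV 7% plus additive SD 0.05 mmol/L,
  a plausible clinical-chemistry assay error (config-exposed; no published
  value to transcribe). With probability 1% a reading is replaced by a
  spurious draw from U(3.5, 7.5) mmol/L, bracketing the kind of improbable
  high value (e.g. 7.28 mmol/L) that outlier screening must catch.
* **Between-subject variability** — off by default: the synthetic cohort
  realises a world in which the supplied PK model is *correct* up to assay
  error, which is what makes the zero-noise closure and bias-recovery checks
  sharp (simulate from θ, validate against θ, recover exactly 0 or exactly
  the injected bias). A log-normal CV on CL and V1 (`bsv_cv`) is available
  for robustness studies.

What it does **not** emulate: delivery events and postpartum timing (duration
is drawn directly), within-case creatinine drift, correlated sampling-time
patterns of real wards, down-titration or clinical interventions after high
readings. Consequently, passing tests demonstrate internal correctness and
recoverability, not clinical performance of any particular parameter set.

## Validation statistics

* Observations are matched to the nearest 5-min grid node of the predicted
  table (offset ≤ 2.5 min by construction); aberrant-flagged readings are
  excluded, as are observations beyond the prediction horizon.
* The prediction error is **signed**, measured − predicted in mmol/L
  (negative mean = model overestimates); the absolute concentration scale is
  kept rather than relative error. The CI is Student-t on the pooled pairs;
  since cases contribute several pairs each, a case-clustered sandwich CI is
  provided as a sensitivity option. No multiplicity adjustment is applied
  anywhere.
* Bias regressions are simple OLS of error on weight, creatinine and
  treatment duration (two-sided t on the slope), via statsmodels.
* Treatment periods: early [0, 4), intermediate [4, 17), late [17, 25),
  extended [25, ∞) h. The conventional period labels leave 16–17 h
  undefined and 25 h doubly assigned; the half-open partition above removes
  both defects and is used everywhere. Adjacent periods are compared with
  Welch's t-test on the per-observation maintenance rate in force at the
  sampling time, and on the measured concentrations.
* Aberrant rule: a reading > 3.5 mmol/L followed within 6 h by a value
  within 0.5 mmol/L of the last pre-spike level is flagged as an erroneous
  measurement. A terminal reading (no follow-up) and a spike with no
  preceding reference are never auto-flagged — they remain in the > 3.5
  toxicity review list, which records for every exceedance whether a later
  sample at or below the threshold "resolved" it.

## Time-to-target analysis

The event is the first non-aberrant **measured** value strictly above
2.0 mmol/L; cases without one are censored at min(last observation, 25 h).
Defining events on measurements mirrors what a retrospective cohort can
observe; it upper-bounds the true crossing time (a predicted-crossing mode
exists for protocol-simulation studies). The Kaplan–Meier estimator,
Greenwood variance with the CI computed on the log-survival scale and
clipped to [0, 1], and the k-group log-rank statistic (hypergeometric
observed-minus-expected with its covariance, χ² on k−1 df) are implemented
directly from the formulas and cross-checked against lifelines in the test
suite. Quartile stratification ranks cases by covariate with case-id
tie-breaks, giving deterministic groups differing in size by at most one.

## Numerical choices

* β is computed as (k10·k21)/α rather than by the subtractive root formula,
  avoiding cancellation for well-separated roots; 1 − e^{−x} uses `expm1`.
* The prediction grid is uniform, includes t = 0, default resolution 5 min;
  threshold crossings are evaluated on the grid without interpolation, so
  results are deterministic under re-gridding only through the resolution.
* Event ties at a time point count events before censorings (standard KM
  convention); bolus events sort before rate changes at equal times.
* Degenerate inputs raise: Q = 0 (one-compartment limit), non-positive
  covariates, schedules not anchored to a first bolus at t = 0, constant
  covariates in quartile stratification.
* Seeds: cohorts derive per-case generators from a master `SeedSequence`, so
  a cohort is reproducible and byte-identical across runs for a fixed seed.

## Problem sizes

The shipped analyses and checks use a 56-case cohort for the end-to-end
study, 500-case cohorts for bias-recovery and quartile-directionality
checks, 100 random parameter/schedule draws for engine-vs-ODE equivalence,
and 1000 replicates for the log-rank null-calibration experiment — sizes at
which the Monte-Carlo error of each check is comfortably below its decision
margin while the whole suite runs in seconds.

## Known limitations

* The typical parameters and covariate forms are placeholders; every
  downstream number in the worked example inherits them.
* With BSV off by default, the validation closure is a consistency check of
  the pipeline, not evidence about any real population.
* The simulator's titration cap (2 g/h) substitutes for unmodelled clinician
  behaviour; real rate trajectories plateau for heterogeneous reasons.
* KM on measured exceedances confounds sampling frequency with kinetics: a
  sparsely sampled case reaches "measured target" later.
* No competing risks: treatment stop and delivery appear only as censoring.
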