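# Default pipeline configuration (RunConfig schema).
#
# The typical PK values below are a PLACEHOLDER parameterisation of the
# two-compartment magnesium sulfate disposition model — transcribe the
# published population PK estimates here before any clinical-mimicking run.
seed: 1
n_cases: 56
resolution: 0.08333333333333333   # 5 min grid
horizon: 60.0                     # prediction horizon (h)
target: 2.0                       # therapeutic target (mmol/L)
toxic: 3.5                        # toxicity review threshold (mmol/L)
km_horizon: 25.0                  # event-analysis horizon (h)
bsv_cv: 0.0
typical:
  CL: 4.0            # L/h
  V1: 20.0           # L
  Q: 2.0             # L/h
  V2: 30.0           # L
  baseline: 0.74     # mmol/L endogenous serum magnesium
  dose_to_amount: 4.06  # mmol elemental Mg per g MgSO4.7H2O
covmodel:
  reference_weight: 70.0       # kg
  reference_creatinine: 60.0   # umol/L
  effects:
    - {parameter: CL, covariate: weight, form: power, value: 0.75}
    - {parameter: CL, covariate: creatinine, form: power, value: -1.0}
    - {parameter: Q, covariate: weight, form: power, value: 0.75}
    - {parameter: V1, covariate: weight, form: power, value: 1.0}
    - {parameter: V2, covariate: weight, form: power, value: 1.0}
protocol:
  bolus_dose: 4.0
  bolus_duration: 0.3333333333333333
  initial_rate: 1.0
  titration_step: 0.25
  titration_threshold: 2.0
  check_delay: 1.0
  max_rate: 2.0
  extra_sample_times: [4.0, 8.0, 12.0, 18.0, 24.0]
  late_sample_interval: 12.0
  max_duration: 60.0
  postpartum_continue: 24.0
error:
  proportional_cv: 0.07
  additive_sd: 0.05
  outlier_prob: 0.01
  outlier_low: 3.5
  outlier_high: 7.5
demographics:
  weight_quartiles: [73.0, 84.0, 95.0]
  creatinine_quartiles: [51.0, 57.0, 69.0]
  gestational_age_quartiles: [33.14, 35.71, 38.43]
  duration_quartiles: [23.7, 29.6, 46.0]
  duration_floor: 6.0
  weight_creatinine_rho: 0.0
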