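# SAPS II point table (17 items) and the published hospital-mortality logit.
# Provenance: transcribed from Le Gall JR et al., JAMA 1993;270:2957-2963.
# Band semantics: [lower, upper, points], lower inclusive, upper exclusive,
# null = unbounded.
system: SAPS2
max_total: 163
age_bands:  # years
  - [null, 40, 0]
  - [40, 60, 7]
  - [60, 70, 12]
  - [70, 75, 15]
  - [75, 80, 16]
  - [80, null, 18]
heart_rate_bands:
  - [null, 40, 11]
  - [40, 70, 2]
  - [70, 120, 0]
  - [120, 160, 4]
  - [160, null, 7]
sbp_bands:  # systolic blood pressure, mmHg
  - [null, 70, 13]
  - [70, 100, 5]
  - [100, 200, 0]
  - [200, null, 2]
temperature_bands:  # degrees C; only high temperature scores
  - [null, 39.0, 0]
  - [39.0, null, 3]
# PaO2/FiO2 (mmHg): scored only when on mechanical ventilation or CPAP.
pf_ratio_bands:
  - [null, 100, 11]
  - [100, 200, 9]
  - [200, null, 6]
urine_output_bands:  # mL/day
  - [null, 500, 11]
  - [500, 1000, 4]
  - [1000, null, 0]
urea_bands:  # BUN mg/dL
  - [null, 28, 0]
  - [28, 84, 6]
  - [84, null, 10]
leukocytes_bands:  # 10^3/uL
  - [null, 1.0, 12]
  - [1.0, 20.0, 0]
  - [20.0, null, 3]
potassium_bands:  # mmol/L
  - [null, 3.0, 3]
  - [3.0, 5.0, 0]
  - [5.0, null, 3]
sodium_bands:  # mmol/L
  - [null, 125, 5]
  - [125, 145, 0]
  - [145, null, 1]
bicarbonate_bands:  # mmol/L
  - [null, 15, 6]
  - [15, 20, 3]
  - [20, null, 0]
bilirubin_bands:  # mg/dL
  - [null, 4.0, 0]
  - [4.0, 6.0, 4]
  - [6.0, null, 9]
gcs_bands:
  - [null, 6, 26]
  - [6, 9, 13]
  - [9, 11, 7]
  - [11, 14, 5]
  - [14, 16, 0]
chronic_disease_points:  # the single worst applicable category scores
  metastatic_cancer: 9
  hematologic_malignancy: 10
  aids: 17
admission_type_points:
  scheduled_surgical: 0
  medical: 6
  unscheduled_surgical: 8
# Published conversion from total points S to hospital-mortality probability:
# logit = b0 + b1*S + b2*ln(S + 1); p = exp(logit) / (1 + exp(logit)).
probability_logit:
  b0: -7.7631
  b1: 0.0737
  b2: 0.9971
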