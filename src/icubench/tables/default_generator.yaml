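# Packaged default GeneratorConfig for the synthetic cardiac-surgery ICU
# cohort. Hazard and demographic parameters are calibrated once (and frozen
# here) to the cohort margins of a large two-year postoperative cardiac
# surgery service: ICU mortality ~5.2%, ICULOS mean ~4.3 d / median 2 d with
# a long right tail, age ~66.9 +/- 10.7 y in [19, 89], 29.6% female, and a
# CABG-dominated surgery mix.
n_stays: 2801
seed: 0
age_mean: 67.7
age_sd: 11.5
age_bounds: [19, 89]
female_prob: 0.296
surgery_mix:
  cabg: 0.545
  isolated_valve: 0.227
  cabg_valve: 0.136
  aorta: 0.021
  aorta_valve: 0.041
  aorta_cabg: 0.002
  transplant: 0.009
  other: 0.019
admission_mix:
  scheduled_surgical: 0.90
  unscheduled_surgical: 0.09
  medical: 0.01
chronic_flag_probs:
  immunocompromise: 0.010
  metastatic_cancer: 0.005
  hematologic_malignancy: 0.004
  aids: 0.0005
  nyha_iv: 0.060
  copd: 0.080
  cirrhosis: 0.005
baseline_shape: 2.0
baseline_scale: 0.92
ar: 0.96
ar_decliner: 1.0
recovery_drift: -0.1
escalation_drift: 0.15
innovation_sd: 1.05
decliner_intercept: -3.08
decliner_slope: 0.5
death_intercept: -7.2
death_slope: 0.55
discharge_intercept: 2.2
discharge_slope: 1.28
discharge_day1_offset: -4.5
max_los: 189
readings_per_day: 3
emission:
  map: {base: 82.0, slope: -4.5, noise_sd: 6.0, lo: 30.0, hi: 130.0}
  sbp: {base: 125.0, slope: -7.0, noise_sd: 9.0, lo: 50.0, hi: 220.0}
  heart_rate: {base: 78.0, slope: 7.0, noise_sd: 8.0, lo: 30.0, hi: 220.0}
  cvp: {base: 6.0, slope: 1.6, noise_sd: 1.5, lo: 0.0, hi: 35.0}
  lactate: {base: 0.9, slope: 0.7, noise_sd: 0.3, lo: 0.3, hi: 25.0}
  fio2: {base: 0.21, slope: 0.055, noise_sd: 0.02, lo: 0.21, hi: 1.0}
  pf_ratio: {base: 430.0, slope: -45.0, noise_sd: 25.0, lo: 40.0, hi: 600.0}
  paco2: {base: 40.0, slope: 0.8, noise_sd: 3.0, lo: 20.0, hi: 90.0}
  respiratory_rate: {base: 15.0, slope: 1.2, noise_sd: 2.0, lo: 6.0, hi: 50.0}
  ph: {base: 7.41, slope: -0.022, noise_sd: 0.02, lo: 6.9, hi: 7.7}
  creatinine: {base: 0.9, slope: 0.28, noise_sd: 0.12, lo: 0.3, hi: 12.0}
  urea: {base: 18.0, slope: 4.5, noise_sd: 4.0, lo: 5.0, hi: 200.0}
  bilirubin: {base: 0.6, slope: 0.35, noise_sd: 0.15, lo: 0.1, hi: 30.0}
  platelets: {base: 230.0, slope: -18.0, noise_sd: 20.0, lo: 5.0, hi: 600.0}
  leukocytes: {base: 9.0, slope: 1.3, noise_sd: 1.5, lo: 0.3, hi: 60.0}
  hematocrit: {base: 36.0, slope: -1.1, noise_sd: 2.0, lo: 12.0, hi: 60.0}
  sodium: {base: 139.0, slope: 1.1, noise_sd: 2.0, lo: 110.0, hi: 175.0}
  potassium: {base: 4.2, slope: 0.18, noise_sd: 0.25, lo: 1.8, hi: 9.0}
  bicarbonate: {base: 24.0, slope: -1.0, noise_sd: 1.2, lo: 5.0, hi: 45.0}
  temperature: {base: 36.9, slope: 0.16, noise_sd: 0.3, lo: 28.0, hi: 42.5}
  urine_output: {base: 2400.0, slope: -230.0, noise_sd: 200.0, lo: 0.0, hi: 6000.0}
device_thresholds:
  mech_ventilation: 2.2
  iabp: 5.5
  vad: 8.0
  dialysis: 6.5
cat_dose_thresholds: [2.0, 4.0, 6.0]
neuro_thresholds: [2.5, 4.5, 6.5, 8.5]
gcs_link: {base: 15.0, slope: 1.1, onset: 2.0, noise_sd: 0.5}
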