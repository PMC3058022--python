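# CASUS (Cardiac Surgery Score) point table: ten daily descriptors, each 0-4,
# designed for postoperative cardiac surgery ICU patients.
# Provenance: reconstructed after Hekmat K et al., Med Sci Monit 2005 (the
# original additive CASUS publication). The ten-descriptor structure merges
# IABP/VAD into a single mechanical-assist descriptor and creatinine/renal
# replacement into a single renal descriptor. This file is versioned data so
# individual band edges can be diffed against the source publication and
# corrected without touching code.
# Band semantics: [lower, upper, points], lower inclusive, upper exclusive,
# null = unbounded.
system: CASUS
max_total: 40
oxygenation:
  pf_ratio_bands:  # PaO2/FiO2, mmHg
    - [250, null, 0]
    - [200, 250, 1]
    - [150, 200, 2]
    - [100, 150, 3]
    - [null, 100, 4]
lactate:
  bands:  # mmol/L
    - [null, 2.0, 0]
    - [2.0, 4.0, 1]
    - [4.0, 6.0, 2]
    - [6.0, 8.0, 3]
    - [8.0, null, 4]
liver:
  bilirubin_bands:  # mg/dL
    - [null, 1.2, 0]
    - [1.2, 2.0, 1]
    - [2.0, 6.0, 2]
    - [6.0, 12.0, 3]
    - [12.0, null, 4]
renal:
  # Creatinine strata 0-3; renal replacement therapy scores 4 outright.
  creatinine_bands:  # mg/dL
    - [null, 1.2, 0]
    - [1.2, 2.0, 1]
    - [2.0, 3.5, 2]
    - [3.5, null, 3]
  dialysis_points: 4
coagulation:
  platelets_bands:  # 10^3/uL
    - [150, null, 0]
    - [100, 150, 1]
    - [50, 100, 2]
    - [20, 50, 3]
    - [null, 20, 4]
blood_pressure:
  map_bands:  # mmHg
    - [60, null, 0]
    - [55, 60, 1]
    - [50, 55, 2]
    - [45, 50, 3]
    - [null, 45, 4]
heart_rate:
  bands:  # beats/min; both tachy- and bradycardia score
    - [60, 111, 0]
    - [111, 131, 1]
    - [50, 60, 1]
    - [131, 151, 2]
    - [40, 50, 2]
    - [151, 181, 3]
    - [30, 40, 3]
    - [181, null, 4]
    - [null, 30, 4]
venous_pressure:
  cvp_bands:  # mmHg
    - [null, 11, 0]
    - [11, 15, 1]
    - [15, 19, 2]
    - [19, 23, 3]
    - [23, null, 4]
neurologic_state:
  # Ordinal bedside assessment, recorded directly (never derived from GCS):
  # 0 alert/oriented, 1 confused or agitated, 2 sedated/responsive,
  # 3 focal neurologic deficit, 4 coma/unresponsive.
  points: {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}
mechanical_assist:
  none_points: 0
  iabp_points: 3
  vad_points: 4  # VAD dominates when both devices are present
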