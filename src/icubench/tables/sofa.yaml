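# SOFA (Sequential Organ Failure Assessment) point table.
# Provenance: transcribed from Vincent JL et al., Intensive Care Med 1996;22:707-710.
# Band semantics throughout: [lower, upper, points], lower inclusive, upper
# exclusive, null = unbounded. Units are the package's canonical clinical units.
system: SOFA
max_total: 24
respiration:
  # PaO2/FiO2 ratio in mmHg; strata 3 and 4 require mechanical ventilation,
  # otherwise the component is capped at the unventilated maximum.
  pf_ratio_bands:
    - [400, null, 0]
    - [300, 400, 1]
    - [200, 300, 2]
    - [100, 200, 3]
    - [null, 100, 4]
  unventilated_cap: 2
coagulation:
  platelets_bands:  # 10^3/uL
    - [150, null, 0]
    - [100, 150, 1]
    - [50, 100, 2]
    - [20, 50, 3]
    - [null, 20, 4]
liver:
  bilirubin_bands:  # mg/dL
    - [null, 1.2, 0]
    - [1.2, 2.0, 1]
    - [2.0, 6.0, 2]
    - [6.0, 12.0, 3]
    - [12.0, null, 4]
cardiovascular:
  # MAP stratum vs catecholamine dose class; the worse of the two applies.
  # Dose classes: 0 none; 1 low (dopamine <=5 ug/kg/min or any dobutamine);
  # 2 mid (dopamine >5 or epi/norepi <=0.1); 3 high (dopamine >15 or
  # epi/norepi >0.1).
  map_bands:  # mmHg
    - [70, null, 0]
    - [null, 70, 1]
  dose_class_points: {0: 0, 1: 2, 2: 3, 3: 4}
cns:
  gcs_bands:
    - [15, 16, 0]
    - [13, 15, 1]
    - [10, 13, 2]
    - [6, 10, 3]
    - [3, 6, 4]
renal:
  creatinine_bands:  # mg/dL
    - [null, 1.2, 0]
    - [1.2, 2.0, 1]
    - [2.0, 3.5, 2]
    - [3.5, 5.0, 3]
    - [5.0, null, 4]
  urine_bands:  # mL/day; the worse of creatinine vs urine applies
    - [500, null, 0]
    - [200, 500, 3]
    - [null, 200, 4]
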