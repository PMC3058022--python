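# APACHE II point table (acute physiology + age + chronic health).
# Provenance: transcribed from Knaus WA et al., Crit Care Med 1985;13:818-829.
# Band semantics: [lower, upper, points], lower inclusive, upper exclusive,
# null = unbounded. Creatinine points are NOT doubled (no acute-renal-failure
# flag in the input vocabulary); serum HCO3 is not used as a physiology item
# because arterial pH is always available in this pipeline.
system: APACHE2
max_total: 71
acute_physiology:
  temperature_bands:  # degrees C, rectal-equivalent core temperature
    - [41.0, null, 4]
    - [39.0, 41.0, 3]
    - [38.5, 39.0, 1]
    - [36.0, 38.5, 0]
    - [34.0, 36.0, 1]
    - [32.0, 34.0, 2]
    - [30.0, 32.0, 3]
    - [null, 30.0, 4]
  map_bands:  # mmHg
    - [160, null, 4]
    - [130, 160, 3]
    - [110, 130, 2]
    - [70, 110, 0]
    - [50, 70, 2]
    - [null, 50, 4]
  heart_rate_bands:
    - [180, null, 4]
    - [140, 180, 3]
    - [110, 140, 2]
    - [70, 110, 0]
    - [55, 70, 2]
    - [40, 55, 3]
    - [null, 40, 4]
  respiratory_rate_bands:
    - [50, null, 4]
    - [35, 50, 3]
    - [25, 35, 1]
    - [12, 25, 0]
    - [10, 12, 1]
    - [6, 10, 2]
    - [null, 6, 4]
  # Oxygenation: if FiO2 >= 0.5 use the alveolar-arterial gradient
  # A-aDO2 = FiO2*713 - PaCO2/0.8 - PaO2 (sea level); otherwise use PaO2.
  fio2_threshold: 0.5
  aado2_bands:  # mmHg
    - [500, null, 4]
    - [350, 500, 3]
    - [200, 350, 2]
    - [null, 200, 0]
  pao2_bands:  # mmHg
    - [71, null, 0]
    - [61, 71, 1]
    - [55, 61, 3]
    - [null, 55, 4]
  ph_bands:
    - [7.70, null, 4]
    - [7.60, 7.70, 3]
    - [7.50, 7.60, 1]
    - [7.33, 7.50, 0]
    - [7.25, 7.33, 2]
    - [7.15, 7.25, 3]
    - [null, 7.15, 4]
  sodium_bands:  # mmol/L
    - [180, null, 4]
    - [160, 180, 3]
    - [155, 160, 2]
    - [150, 155, 1]
    - [130, 150, 0]
    - [120, 130, 2]
    - [111, 120, 3]
    - [null, 111, 4]
  potassium_bands:  # mmol/L
    - [7.0, null, 4]
    - [6.0, 7.0, 3]
    - [5.5, 6.0, 1]
    - [3.5, 5.5, 0]
    - [3.0, 3.5, 1]
    - [2.5, 3.0, 2]
    - [null, 2.5, 4]
  creatinine_bands:  # mg/dL
    - [3.5, null, 4]
    - [2.0, 3.5, 3]
    - [1.5, 2.0, 2]
    - [0.6, 1.5, 0]
    - [null, 0.6, 2]
  hematocrit_bands:  # %
    - [60.0, null, 4]
    - [50.0, 60.0, 2]
    - [46.0, 50.0, 1]
    - [30.0, 46.0, 0]
    - [20.0, 30.0, 2]
    - [null, 20.0, 4]
  leukocytes_bands:  # 10^3/uL
    - [40.0, null, 4]
    - [20.0, 40.0, 2]
    - [15.0, 20.0, 1]
    - [3.0, 15.0, 0]
    - [1.0, 3.0, 2]
    - [null, 1.0, 4]
  # Glasgow Coma Scale contributes (15 - GCS) points.
age_bands:  # years
  - [null, 45, 0]
  - [45, 55, 2]
  - [55, 65, 3]
  - [65, 75, 5]
  - [75, null, 6]
chronic_health:
  # Any qualifying severe chronic organ insufficiency or immunocompromise.
  qualifying_flags:
    - immunocompromise
    - metastatic_cancer
    - hematologic_malignancy
    - aids
    - nyha_iv
    - copd
    - cirrhosis
  points_elective_postop: 2
  points_other: 5  # nonoperative or emergency postoperative
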