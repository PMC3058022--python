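"""Hand-scored fixture panels: the table-lookup oracle for every engine.

Each case was scored by hand against the packaged point tables (band by
band, selecting for bidirectional variables the daily extreme worth the
most points) and the expected total frozen here. The engines must
reproduce every total exactly.

A case is (label, system, panel_kwargs, stay_kwargs, expected_total);
panel/stay kwargs feed tests.conftest.make_panel / make_stay.
"""

SOFA_CASES = [
    ("all normal", {}, {}, 0),
    # PaO2 60 / FiO2 0.6 = 100 -> stratum 3, ventilated
    ("resp pf 100 ventilated", {"pao2": 60, "fio2": 0.6,
                                "flags": {"mech_ventilation": True}}, {}, 3),
    # PaO2 55 / FiO2 0.8 = 68.75 -> stratum 4 but capped at 2 unventilated
    ("resp pf 69 unventilated cap", {"pao2": (55, 95), "fio2": (0.21, 0.8)}, {}, 2),
    ("platelets min 45", {"platelets": (45, 120)}, {}, 3),
    ("bilirubin max 6.2", {"bilirubin": (0.5, 6.2)}, {}, 3),
    # MAP 65 -> 1 vs catecholamine class 2 -> 3; worse applies
    ("cardio dose class beats MAP", {"map": (65, 80),
                                     "catecholamine_dose_class": 2}, {}, 3),
    ("gcs 12", {"gcs": 12}, {}, 2),
    ("creatinine max 2.1", {"creatinine": (1.0, 2.1)}, {}, 2),
    ("oliguria 450 mL", {"urine_output": 450}, {}, 3),
    # 3 resp + 2 coag + 2 liver + 4 cardio + 3 cns + 3 renal = 17
    ("mixed severe", {"pao2": (70, 90), "fio2": 0.5, "platelets": (90, 110),
                      "bilirubin": (1.0, 2.5), "map": (55, 70),
                      "catecholamine_dose_class": 3, "gcs": 9,
                      "creatinine": 3.6, "urine_output": 300,
                      "flags": {"mech_ventilation": True}}, {}, 17),
    ("ceiling 24", {"pao2": 40, "fio2": 1.0, "platelets": 10, "bilirubin": 15,
                    "map": 40, "catecholamine_dose_class": 3, "gcs": 3,
                    "creatinine": 6.0, "urine_output": 100,
                    "flags": {"mech_ventilation": True}}, {}, 24),
]

APACHE2_CASES = [
    ("all normal young elective", {}, {"age": 40}, 0),
    ("gcs 10 adds 5", {"gcs": 10}, {"age": 40}, 5),
    ("fever 38.7", {"temperature": 38.7}, {"age": 40}, 1),
    ("temp extremes 35/38.6 worst 1", {"temperature": (35.0, 38.6)}, {"age": 40}, 1),
    ("map extremes 45/120 worst 4", {"map": (45, 120)}, {"age": 40}, 4),
    ("hr extremes 50/125 worst 3", {"heart_rate": (50, 125)}, {"age": 40}, 3),
    ("rr extremes 8/30 worst 2", {"respiratory_rate": (8, 30)}, {"age": 40}, 2),
    # FiO2 0.6 >= 0.5: A-aDO2 = 0.6*713 - 36/0.8 - 65 = 317.8 -> 2
    ("aado2 318", {"fio2": (0.21, 0.6), "pao2": (65, 90), "paco2": (36, 40)},
     {"age": 40}, 2),
    ("hypoxemia pao2 58 low fio2", {"pao2": (58, 70)}, {"age": 40}, 3),
    ("ph extremes 7.28/7.52 worst 2", {"ph": (7.28, 7.52)}, {"age": 40}, 2),
    ("sodium extremes 128/156 worst 2", {"sodium": (128, 156)}, {"age": 40}, 2),
    ("potassium extremes 3.2/6.1 worst 3", {"potassium": (3.2, 6.1)}, {"age": 40}, 3),
    ("creatinine extremes 0.5/1.8 worst 2", {"creatinine": (0.5, 1.8)}, {"age": 40}, 2),
    ("hematocrit extremes 22/47 worst 2", {"hematocrit": (22, 47)}, {"age": 40}, 2),
    ("wbc extremes 2.5/21 worst 2", {"leukocytes": (2.5, 21)}, {"age": 40}, 2),
    # age 70 -> 5; chronic + unscheduled surgical -> 5
    ("age 70 emergency copd", {}, {"age": 70, "admission_category":
                                   "unscheduled_surgical",
                                   "chronic_health_flags": ("copd",)}, 10),
    # age 70 -> 5; chronic + elective postoperative -> 2
    ("age 70 elective copd", {}, {"age": 70,
                                  "chronic_health_flags": ("copd",)}, 7),
    # APS 3+2+3 = 8; age 78 -> 6; medical + cirrhosis -> 5
    ("combined 19", {"gcs": 12, "map": 60, "creatinine": 2.4},
     {"age": 78, "admission_category": "medical",
      "chronic_health_flags": ("cirrhosis",)}, 19),
]

SAPS2_CASES = [
    ("all normal young scheduled", {}, {"age": 35}, 0),
    # PaO2 95 / FiO2 0.5 = 190 -> 9, only because ventilated
    ("ventilated pf 190", {"pao2": 95, "fio2": 0.5,
                           "flags": {"mech_ventilation": True}}, {"age": 35}, 9),
    ("same panel unventilated", {"pao2": 95, "fio2": 0.5}, {"age": 35}, 0),
    ("age 45", {}, {"age": 45}, 7),
    ("age 62 medical", {}, {"age": 62, "admission_category": "medical"}, 18),
    ("bradycardia 35", {"heart_rate": (35, 90)}, {"age": 35}, 11),
    ("hr extremes 65/165 worst 7", {"heart_rate": (65, 165)}, {"age": 35}, 7),
    ("sbp extremes 85/210 worst 5", {"sbp": (85, 210)}, {"age": 35}, 5),
    ("fever 39.5", {"temperature": (36.0, 39.5)}, {"age": 35}, 3),
    ("oliguria 450 mL", {"urine_output": 450}, {"age": 35}, 11),
    ("urea max 90", {"urea": (30, 90)}, {"age": 35}, 10),
    ("leukopenia 0.8", {"leukocytes": (0.8, 12)}, {"age": 35}, 12),
    ("potassium extremes both abnormal", {"potassium": (2.8, 5.2)}, {"age": 35}, 3),
    ("sodium extremes 124/146 worst 5", {"sodium": (124, 146)}, {"age": 35}, 5),
    ("bicarbonate 14", {"bicarbonate": (14, 22)}, {"age": 35}, 6),
    ("bilirubin 4.5", {"bilirubin": (0.5, 4.5)}, {"age": 35}, 4),
    ("gcs 10", {"gcs": 10}, {"age": 35}, 7),
    ("gcs 13", {"gcs": 13}, {"age": 35}, 5),
    # worst chronic category (hematologic 10) + unscheduled surgical 8
    ("chronic + emergency", {}, {"age": 35, "admission_category":
                                 "unscheduled_surgical",
                                 "chronic_health_flags":
                                 ("metastatic_cancer", "hematologic_malignancy")}, 18),
    # 18+4+13+3+9+4+10+3+3+5+6+9+13+17+6 = 123
    ("near-worst composite", {"heart_rate": 130, "sbp": 65, "temperature": 39.2,
                              "pao2": 80, "fio2": 0.8, "urine_output": 800,
                              "urea": 85, "leukocytes": 25, "potassium": 5.5,
                              "sodium": 120, "bicarbonate": 12, "bilirubin": 7.0,
                              "gcs": 8, "flags": {"mech_ventilation": True}},
     {"age": 81, "admission_category": "medical",
      "chronic_health_flags": ("aids",)}, 123),
]

CASUS_CASES = [
    ("all normal", {}, {}, 0),
    ("iabp", {"flags": {"iabp": True}}, {}, 3),
    ("vad dominates iabp", {"flags": {"iabp": True, "vad": True}}, {}, 4),
    ("renal replacement", {"flags": {"dialysis": True}}, {}, 4),
    # PaO2 60 / FiO2 0.4 = 150 -> 2
    ("pf 150", {"pao2": 60, "fio2": 0.4}, {}, 2),
    ("lactate max 4.5", {"lactate": (1.0, 4.5)}, {}, 2),
    ("bilirubin 2.5", {"bilirubin": 2.5}, {}, 2),
    ("creatinine 3.6 without dialysis", {"creatinine": (1.5, 3.6)}, {}, 3),
    ("platelets min 40", {"platelets": (40, 200)}, {}, 3),
    ("map min 47", {"map": (47, 90)}, {}, 3),
    ("hr extremes 55/140 worst 2", {"heart_rate": (55, 140)}, {}, 2),
    ("cvp max 16", {"cvp": (5, 16)}, {}, 2),
    ("neurologic deficit", {"neurologic_state": 3}, {}, 3),
    ("ceiling 40", {"pao2": 45, "fio2": 0.5, "lactate": 9.0, "bilirubin": 13.0,
                    "platelets": 15, "map": 42, "heart_rate": 185, "cvp": 25,
                    "neurologic_state": 4,
                    "flags": {"dialysis": True, "vad": True}}, {}, 40),
]

ALL_CASES = (
    [("SOFA",) + c for c in SOFA_CASES]
    + [("APACHE2",) + c for c in APACHE2_CASES]
    + [("SAPS2",) + c for c in SAPS2_CASES]
    + [("CASUS",) + c for c in CASUS_CASES]
)
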