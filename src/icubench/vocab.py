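"""Controlled vocabulary of daily physiological variables.

Every observation fed to the scoring engines must use one of the variable
names below. Values are stored internally in the *canonical* unit of each
variable — conventional clinical units, because the published point tables
of all four scoring systems are stated in them. SI inputs are converted on
load via :data:`UNIT_CONVERSIONS`.

``NORMAL_VALUES`` holds the zero-point ("assume normal") value used when a
variable is missing for a stay-day and imputation is enabled.
"""

from __future__ import annotations

#: Continuous variables: the daily reduction keeps both extremes (min, max)
#: so each scoring engine can pick the extreme worth the most points.
CONTINUOUS = (
    "map",
    "sbp",
    "heart_rate",
    "cvp",
    "lactate",
    "pao2",
    "fio2",
    "paco2",
    "respiratory_rate",
    "ph",
    "creatinine",
    "urea",
    "bilirubin",
    "platelets",
    "leukocytes",
    "hematocrit",
    "sodium",
    "potassium",
    "bicarbonate",
    "temperature",
)

#: Summed over the day (mL collected), not reduced to an extreme.
CUMULATIVE = ("urine_output",)

#: Ordinal variables with a fixed worst-direction reduction.
#: GCS: daily minimum (worst consciousness); neurologic state and
#: catecholamine dose class: daily maximum (worst stratum).
ORDINAL_MIN = ("gcs",)
ORDINAL_MAX = ("neurologic_state", "catecholamine_dose_class")

#: Support/device flags, OR-ed over the day.
FLAGS = ("mech_ventilation", "iabp", "vad", "dialysis")

VOCABULARY = CONTINUOUS + CUMULATIVE + ORDINAL_MIN + ORDINAL_MAX + FLAGS

#: Canonical unit per variable (conventional clinical units).
CANONICAL_UNITS = {
    "map": "mmHg",
    "sbp": "mmHg",
    "heart_rate": "/min",
    "cvp": "mmHg",
    "lactate": "mmol/L",
    "pao2": "mmHg",
    "fio2": "fraction",
    "paco2": "mmHg",
    "respiratory_rate": "/min",
    "ph": "unitless",
    "creatinine": "mg/dL",
    "urea": "mg/dL",  # blood urea nitrogen scale
    "urine_output": "mL/day",
    "bilirubin": "mg/dL",
    "platelets": "10^3/uL",
    "leukocytes": "10^3/uL",
    "hematocrit": "%",
    "sodium": "mmol/L",
    "potassium": "mmol/L",
    "bicarbonate": "mmol/L",
    "temperature": "C",
    "gcs": "points",
    "neurologic_state": "ordinal",
    "catecholamine_dose_class": "ordinal",
    "mech_ventilation": "flag",
    "iabp": "flag",
    "vad": "flag",
    "dialysis": "flag",
}

#: (variable, unit) -> callable converting to the canonical unit.
#: Identity conversions for the canonical unit itself are implicit.
UNIT_CONVERSIONS = {
    ("creatinine", "umol/L"): lambda v: v / 88.4,
    ("bilirubin", "umol/L"): lambda v: v / 17.1,
    ("urea", "mmol/L"): lambda v: v * 2.8,  # urea mmol/L -> BUN mg/dL
    ("pao2", "kPa"): lambda v: v * 7.50062,
    ("paco2", "kPa"): lambda v: v * 7.50062,
    ("fio2", "%"): lambda v: v / 100.0,
    ("hematocrit", "fraction"): lambda v: v * 100.0,
    ("temperature", "F"): lambda v: (v - 32.0) * 5.0 / 9.0,
    ("urine_output", "L/day"): lambda v: v * 1000.0,
    ("platelets", "10^9/L"): lambda v: v,  # numerically identical
    ("leukocytes", "10^9/L"): lambda v: v,
}

#: Zero-point values: the value each scoring system scores as normal.
NORMAL_VALUES = {
    "map": 80.0,
    "sbp": 120.0,
    "heart_rate": 80.0,
    "cvp": 6.0,
    "lactate": 1.0,
    "pao2": 95.0,
    "fio2": 0.21,
    "paco2": 40.0,
    "respiratory_rate": 16.0,
    "ph": 7.40,
    "creatinine": 0.9,
    "urea": 20.0,
    "urine_output": 2000.0,
    "bilirubin": 0.7,
    "platelets": 250.0,
    "leukocytes": 8.0,
    "hematocrit": 40.0,
    "sodium": 140.0,
    "potassium": 4.2,
    "bicarbonate": 24.0,
    "temperature": 37.0,
    "gcs": 15,
    "neurologic_state": 0,
    "catecholamine_dose_class": 0,
    "mech_ventilation": False,
    "iabp": False,
    "vad": False,
    "dialysis": False,
}

#: The eight surgery categories of a cardiac-surgery ICU case mix.
SURGERY_TYPES = (
    "cabg",
    "isolated_valve",
    "cabg_valve",
    "aorta",
    "aorta_valve",
    "aorta_cabg",
    "transplant",
    "other",
)

ADMISSION_CATEGORIES = ("scheduled_surgical", "unscheduled_surgical", "medical")

#: Comorbidity flags consumed by the APACHE II and SAPS II chronic-health items.
CHRONIC_FLAGS = (
    "immunocompromise",
    "metastatic_cancer",
    "hematologic_malignancy",
    "aids",
    "nyha_iv",
    "copd",
    "cirrhosis",
)

OUTCOMES = ("icu_death", "icu_survival")


def convert_to_canonical(variable: str, value: float, unit: str) -> float:
    """Convert ``value`` of ``variable`` expressed in ``unit`` to the canonical unit.

    Raises
    ------
    KeyError
        If the variable is not in the vocabulary.
    ValueError
        If the unit is neither canonical nor convertible.
    """
    canonical = CANONICAL_UNITS[variable]
    if unit == canonical:
        return float(value)
    conv = UNIT_CONVERSIONS.get((variable, unit))
    if conv is None:
        raise ValueError(
            f"unit {unit!r} for variable {variable!r} is not convertible "
            f"to canonical unit {canonical!r}"
        )
    return float(conv(float(value)))
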