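import pandas as pd
import pytest

from icubench import vocab
from icubench.cohort import DailyWorstPanel, StayRecord


def make_panel(stay_id="S1", day=1, urine_output=None, gcs=15, neurologic_state=0,
               catecholamine_dose_class=0, flags=None, **variables):
    """Panel with every variable at its normal value unless overridden.

    Continuous overrides accept a scalar (both extremes equal) or a
    (min, max) pair.
    """
    extremes = {}
    for var in vocab.CONTINUOUS:
        v = variables.pop(var, vocab.NORMAL_VALUES[var])
        extremes[var] = tuple(v) if isinstance(v, (tuple, list)) else (float(v), float(v))
    if variables:
        raise TypeError(f"unknown variables {sorted(variables)}")
    all_flags = {f: False for f in vocab.FLAGS}
    all_flags.update(flags or {})
    return DailyWorstPanel(
        stay_id=stay_id,
        day=day,
        extremes=extremes,
        urine_output=float(
            urine_output if urine_output is not None else vocab.NORMAL_VALUES["urine_output"]
        ),
        gcs=gcs,
        neurologic_state=neurologic_state,
        catecholamine_dose_class=catecholamine_dose_class,
        flags=all_flags,
    )


def make_stay(stay_id="S1", age=40, sex="male", surgery_type="cabg",
              admission_category="scheduled_surgical", outcome="icu_survival",
              iculos=1, chronic_health_flags=(), **kwargs):
    return StayRecord(
        stay_id=stay_id,
        age=age,
        sex=sex,
        surgery_type=surgery_type,
        admission_category=admission_category,
        outcome=outcome,
        iculos=iculos,
        chronic_health_flags=frozenset(chronic_health_flags),
        **kwargs,
    )


@pytest.fixture
def two_stay_files(tmp_path):
    """Well-formed two-stay fixture CSVs (one 2-day stay, one 1-day stay)."""
    stays = pd.DataFrame(
        [
            {
                "stay_id": "A", "patient_id": "P1",
                "admission_datetime": "2007-01-05T08:00:00",
                "age": 64, "sex": "male", "surgery_type": "cabg",
                "admission_category": "scheduled_surgical",
                "outcome": "icu_survival", "iculos": 2,
            },
            {
                "stay_id": "B", "patient_id": "P2",
                "admission_datetime": "2007-02-01T09:00:00",
                "age": 71, "sex": "female", "surgery_type": "isolated_valve",
                "admission_category": "unscheduled_surgical",
                "outcome": "icu_death", "iculos": 1,
            },
        ]
    )
    obs = pd.DataFrame(
        [
            ("A", 1, "map", 75.0, "mmHg"),
            ("A", 1, "creatinine", 106.08, "umol/L"),  # 1.2 mg/dL
            ("A", 1, "gcs", 15, "points"),
            ("A", 2, "map", 82.0, "mmHg"),
            ("A", 2, "gcs", 15, "points"),
            ("B", 1, "map", 55.0, "mmHg"),
            ("B", 1, "lactate", 6.5, "mmol/L"),
            ("B", 1, "gcs", 9, "points"),
            ("B", 1, "mech_ventilation", 1, "flag"),
        ],
        columns=["stay_id", "day", "variable", "value", "unit"],
    )
    stays_path = tmp_path / "stays.csv"
    obs_path = tmp_path / "observations.csv"
    stays.to_csv(stays_path, index=False)
    obs.to_csv(obs_path, index=False)
    return stays_path, obs_path
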