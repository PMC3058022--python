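"""Daily scoring engines: CASUS, SOFA, APACHE II and SAPS II.

Each engine maps one :class:`~icubench.cohort.DailyWorstPanel` (plus, for
APACHE II and SAPS II, admission-level covariates from the
:class:`~icubench.cohort.StayRecord`) to a :class:`ScorePanel` holding the
total and the per-component breakdown. Point tables are shipped as
versioned YAML data under ``icubench/tables`` and loaded once per process.

For bidirectional variables the panel carries both daily extremes and each
engine evaluates its own band table at both, keeping the larger point value
— the per-score "most abnormal value of the day". All published band
functions are quasiconvex around the normal range, so the daily maximum of
points over all raw readings is always attained at one of the two extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml

SYSTEMS = ("CASUS", "SOFA", "SAPS2", "APACHE2")


@dataclass(frozen=True)
class ScorePanel:
    """Daily total and component breakdown for one stay-day and one system."""

    stay_id: str
    day: int
    system: str
    total: int
    components: dict

    def __post_init__(self) -> None:
        if self.total != sum(self.components.values()):
            raise ValueError(
                f"{self.system} ({self.stay_id}, day {self.day}): total "
                f"{self.total} != sum of components"
            )


@dataclass(frozen=True)
class ScoreSummary:
    """Mean- and Max-score derivatives of one stay under one system."""

    stay_id: str
    system: str
    mean_score: float
    max_score: int
    iculos: int


@lru_cache(maxsize=None)
def load_table(system: str) -> dict:
    """Load the published point table of ``system`` from the packaged YAML."""
    name = {"SOFA": "sofa", "APACHE2": "apache2", "SAPS2": "saps2", "CASUS": "casus"}[
        system
    ]
    text = resources.files("icubench.tables").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def band_points(bands, value: float) -> int:
    """Look up ``value`` in a [lower, upper, points] band list.

    Lower bounds are inclusive, upper bounds exclusive, ``null`` unbounded.
    """
    for lo, hi, pts in bands:
        if (lo is None or value >= lo) and (hi is None or value < hi):
            return int(pts)
    raise ValueError(f"value {value} not covered by band table")


def worst_points(bands, extremes) -> int:
    """Largest point value over the day's (min, max) extremes."""
    lo, hi = extremes
    return max(band_points(bands, lo), band_points(bands, hi))


def pf_ratio(panel) -> float:
    """Worst PaO2/FiO2 of the day: lowest PaO2 over highest FiO2."""
    return panel.vmin("pao2") / panel.vmax("fio2")


# ---------------------------------------------------------------------------
# SOFA


def score_sofa(panel) -> ScorePanel:
    """Six organ components, each 0-4; total 0-24."""
    t = load_table("SOFA")
    ventilated = panel.flags.get("mech_ventilation", False)
    resp = band_points(t["respiration"]["pf_ratio_bands"], pf_ratio(panel))
    if not ventilated:
        resp = min(resp, int(t["respiration"]["unventilated_cap"]))
    coag = band_points(t["coagulation"]["platelets_bands"], panel.vmin("platelets"))
    liver = band_points(t["liver"]["bilirubin_bands"], panel.vmax("bilirubin"))
    cardio = max(
        band_points(t["cardiovascular"]["map_bands"], panel.vmin("map")),
        int(t["cardiovascular"]["dose_class_points"][panel.catecholamine_dose_class]),
    )
    cns = band_points(t["cns"]["gcs_bands"], panel.gcs)
    renal = max(
        band_points(t["renal"]["creatinine_bands"], panel.vmax("creatinine")),
        band_points(t["renal"]["urine_bands"], panel.urine_output),
    )
    components = {
        "respiration": resp,
        "coagulation": coag,
        "liver": liver,
        "cardiovascular": cardio,
        "cns": cns,
        "renal": renal,
    }
    return ScorePanel(panel.stay_id, panel.day, "SOFA", sum(components.values()), components)


# ---------------------------------------------------------------------------
# APACHE II


def _apache_oxygenation(t: dict, panel) -> int:
    fio2 = panel.vmax("fio2")
    if fio2 >= t["fio2_threshold"]:
        aado2 = fio2 * 713.0 - panel.vmin("paco2") / 0.8 - panel.vmin("pao2")
        return band_points(t["aado2_bands"], aado2)
    return band_points(t["pao2_bands"], panel.vmin("pao2"))


def score_apache2(panel, stay) -> ScorePanel:
    """Acute physiology + age + chronic health points, scored daily.

    The admission-type and chronic-health components are admission-level and
    held constant across the stay's days; GCS contributes 15 - GCS points.
    """
    t = load_table("APACHE2")
    aps_t = t["acute_physiology"]
    aps = (
        worst_points(aps_t["temperature_bands"], panel.extremes["temperature"])
        + worst_points(aps_t["map_bands"], panel.extremes["map"])
        + worst_points(aps_t["heart_rate_bands"], panel.extremes["heart_rate"])
        + worst_points(
            aps_t["respiratory_rate_bands"], panel.extremes["respiratory_rate"]
        )
        + _apache_oxygenation(aps_t, panel)
        + worst_points(aps_t["ph_bands"], panel.extremes["ph"])
        + worst_points(aps_t["sodium_bands"], panel.extremes["sodium"])
        + worst_points(aps_t["potassium_bands"], panel.extremes["potassium"])
        + worst_points(aps_t["creatinine_bands"], panel.extremes["creatinine"])
        + worst_points(aps_t["hematocrit_bands"], panel.extremes["hematocrit"])
        + worst_points(aps_t["leukocytes_bands"], panel.extremes["leukocytes"])
        + (15 - panel.gcs)
    )
    age = band_points(t["age_bands"], stay.age)
    ch = t["chronic_health"]
    if set(stay.chronic_health_flags) & set(ch["qualifying_flags"]):
        chronic = (
            int(ch["points_elective_postop"])
            if stay.admission_category == "scheduled_surgical"
            else int(ch["points_other"])
        )
    else:
        chronic = 0
    components = {"acute_physiology": aps, "age": age, "chronic_health": chronic}
    return ScorePanel(
        panel.stay_id, panel.day, "APACHE2", sum(components.values()), components
    )


# ---------------------------------------------------------------------------
# SAPS II


def score_saps2(panel, stay) -> ScorePanel:
    """The 17-item SAPS II total; oxygenation scored only when ventilated."""
    t = load_table("SAPS2")
    components = {
        "age": band_points(t["age_bands"], stay.age),
        "heart_rate": worst_points(t["heart_rate_bands"], panel.extremes["heart_rate"]),
        "sbp": worst_points(t["sbp_bands"], panel.extremes["sbp"]),
        "temperature": band_points(t["temperature_bands"], panel.vmax("temperature")),
        "oxygenation": (
            band_points(t["pf_ratio_bands"], pf_ratio(panel))
            if panel.flags.get("mech_ventilation", False)
            else 0
        ),
        "urine_output": band_points(t["urine_output_bands"], panel.urine_output),
        "urea": band_points(t["urea_bands"], panel.vmax("urea")),
        "leukocytes": worst_points(t["leukocytes_bands"], panel.extremes["leukocytes"]),
        "potassium": worst_points(t["potassium_bands"], panel.extremes["potassium"]),
        "sodium": worst_points(t["sodium_bands"], panel.extremes["sodium"]),
        "bicarbonate": band_points(t["bicarbonate_bands"], panel.vmin("bicarbonate")),
        "bilirubin": band_points(t["bilirubin_bands"], panel.vmax("bilirubin")),
        "gcs": band_points(t["gcs_bands"], panel.gcs),
        "chronic_disease": max(
            (
                int(pts)
                for flag, pts in t["chronic_disease_points"].items()
                if flag in stay.chronic_health_flags
            ),
            default=0,
        ),
        "admission_type": int(t["admission_type_points"][stay.admission_category]),
    }
    return ScorePanel(
        panel.stay_id, panel.day, "SAPS2", sum(components.values()), components
    )


def saps2_probability(total: int) -> float:
    """Published SAPS II points -> hospital-mortality probability transform.

    Exposed for completeness; the benchmark recalibrates all systems with a
    uniform per-day logistic fit instead of using this native transform.
    """
    t = load_table("SAPS2")["probability_logit"]
    logit = t["b0"] + t["b1"] * total + t["b2"] * math.log(total + 1.0)
    return 1.0 / (1.0 + math.exp(-logit))


# ---------------------------------------------------------------------------
# CASUS


def score_casus(panel) -> ScorePanel:
    """Ten routinely available descriptors for postoperative cardiac patients."""
    t = load_table("CASUS")
    if panel.flags.get("dialysis", False):
        renal = int(t["renal"]["dialysis_points"])
    else:
        renal = worst_points(t["renal"]["creatinine_bands"], panel.extremes["creatinine"])
    assist_t = t["mechanical_assist"]
    if panel.flags.get("vad", False):
        assist = int(assist_t["vad_points"])
    elif panel.flags.get("iabp", False):
        assist = int(assist_t["iabp_points"])
    else:
        assist = int(assist_t["none_points"])
    components = {
        "oxygenation": band_points(t["oxygenation"]["pf_ratio_bands"], pf_ratio(panel)),
        "lactate": worst_points(t["lactate"]["bands"], panel.extremes["lactate"]),
        "liver": band_points(t["liver"]["bilirubin_bands"], panel.vmax("bilirubin")),
        "renal": renal,
        "coagulation": band_points(
            t["coagulation"]["platelets_bands"], panel.vmin("platelets")
        ),
        "blood_pressure": band_points(t["blood_pressure"]["map_bands"], panel.vmin("map")),
        "heart_rate": worst_points(t["heart_rate"]["bands"], panel.extremes["heart_rate"]),
        "venous_pressure": band_points(t["venous_pressure"]["cvp_bands"], panel.vmax("cvp")),
        "neurologic_state": int(t["neurologic_state"]["points"][panel.neurologic_state]),
        "mechanical_assist": assist,
    }
    return ScorePanel(
        panel.stay_id, panel.day, "CASUS", sum(components.values()), components
    )


# ---------------------------------------------------------------------------
# Dispatch and cohort-level tables

_ENGINES = {
    "SOFA": lambda panel, stay: score_sofa(panel),
    "APACHE2": score_apache2,
    "SAPS2": score_saps2,
    "CASUS": lambda panel, stay: score_casus(panel),
}


def score_panel(panel, stay, system: str) -> ScorePanel:
    """Score one stay-day under one system."""
    return _ENGINES[system](panel, stay)


def score_cohort(cohort, systems=SYSTEMS) -> pd.DataFrame:
    """Tidy per stay-day score table: stay_id, day, system, total + components."""
    rows = []
    for stay in cohort.stays:
        for day in range(1, stay.iculos + 1):
            panel = cohort.panels[(stay.stay_id, day)]
            for system in systems:
                sp = score_panel(panel, stay, system)
                row = {
                    "stay_id": sp.stay_id,
                    "day": sp.day,
                    "system": sp.system,
                    "total": sp.total,
                }
                row.update(sp.components)
                rows.append(row)
    frame = pd.DataFrame(rows)
    lead = ["stay_id", "day", "system", "total"]
    return frame[lead + [c for c in frame.columns if c not in lead]]


def derive_summary(daily_totals, stay_id: str = "?", system: str = "?") -> ScoreSummary:
    """Mean- and Max-score over one stay's ordered daily totals.

    Mean-score = sum of daily values / ICU length of stay (in scored days);
    Max-score = the worst (largest) daily total of the stay.
    """
    totals = list(daily_totals)
    if not totals:
        raise ValueError("derive_summary: empty daily total list")
    return ScoreSummary(
        stay_id=stay_id,
        system=system,
        mean_score=sum(totals) / len(totals),
        max_score=int(max(totals)),
        iculos=len(totals),
    )


def summarize_scores(score_table: pd.DataFrame) -> pd.DataFrame:
    """Per-stay Mean/Max derivative table from a tidy daily score table."""
    rows = []
    for (sid, system), grp in score_table.groupby(["stay_id", "system"], sort=False):
        totals = grp.sort_values("day")["total"].tolist()
        s = derive_summary(totals, stay_id=sid, system=system)
        rows.append(
            {
                "stay_id": s.stay_id,
                "system": s.system,
                "mean_score": s.mean_score,
                "max_score": s.max_score,
                "iculos": s.iculos,
            }
        )
    return pd.DataFrame(rows)
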