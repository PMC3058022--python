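"""Cohort data model: ICU stays, daily observations and worst-value panels.

A cohort is a set of postoperative ICU stays (one :class:`StayRecord` per
stay) plus long-format daily physiological observations. Before scoring,
the raw repeated measurements of each stay-day are reduced to a
:class:`DailyWorstPanel`: both daily extremes of every continuous variable
(so each scoring engine can independently select the extreme worth the most
points), summed urine output, OR-ed device flags, the daily minimum GCS and
the daily maximum ordinal strata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from . import vocab

logger = logging.getLogger(__name__)


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A row violates the CSV schema (unknown variable, non-numeric value...)."""


class UnitError(CohortError):
    """An observation's unit cannot be converted to the canonical unit."""


class ConsistencyError(CohortError):
    """Cross-file referential or day-count inconsistency."""


class MissingDataError(CohortError):
    """A required variable is absent and strict mode forbids imputation."""


@dataclass(frozen=True)
class StayRecord:
    """One ICU admission after first-admission filtering."""

    stay_id: str
    age: int
    sex: str  # "female" | "male"
    surgery_type: str
    admission_category: str
    outcome: str  # "icu_death" | "icu_survival"
    iculos: int
    chronic_health_flags: frozenset = frozenset()
    euroscore_additive: float | None = None
    euroscore_logistic: float | None = None
    patient_id: str | None = None
    admission_datetime: str | None = None

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 120:
            raise CohortError(f"stay {self.stay_id}: age {self.age} outside [18, 120]")
        if self.sex not in ("female", "male"):
            raise CohortError(f"stay {self.stay_id}: unknown sex {self.sex!r}")
        if self.surgery_type not in vocab.SURGERY_TYPES:
            raise CohortError(
                f"stay {self.stay_id}: unknown surgery_type {self.surgery_type!r}"
            )
        if self.admission_category not in vocab.ADMISSION_CATEGORIES:
            raise CohortError(
                f"stay {self.stay_id}: unknown admission_category "
                f"{self.admission_category!r}"
            )
        if self.outcome not in vocab.OUTCOMES:
            raise CohortError(f"stay {self.stay_id}: unknown outcome {self.outcome!r}")
        if self.iculos < 1:
            raise CohortError(f"stay {self.stay_id}: iculos {self.iculos} < 1")
        unknown = set(self.chronic_health_flags) - set(vocab.CHRONIC_FLAGS)
        if unknown:
            raise CohortError(f"stay {self.stay_id}: unknown chronic flags {unknown}")
        if self.euroscore_logistic is not None and not 0 <= self.euroscore_logistic <= 1:
            raise CohortError(
                f"stay {self.stay_id}: euroscore_logistic outside [0, 1]"
            )

    @property
    def died(self) -> bool:
        return self.outcome == "icu_death"


@dataclass(frozen=True)
class DailyWorstPanel:
    """Per stay-day reduction of raw observations.

    ``extremes`` maps every continuous variable to its (daily min, daily max)
    in canonical units. Variables listed in ``imputed`` were absent that day
    and filled with their normal (zero-point) value.
    """

    stay_id: str
    day: int
    extremes: dict  # variable -> (vmin, vmax)
    urine_output: float
    gcs: int
    neurologic_state: int
    catecholamine_dose_class: int
    flags: dict  # flag name -> bool
    imputed: frozenset = frozenset()

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.extremes.items():
            if lo > hi:
                raise CohortError(
                    f"panel ({self.stay_id}, day {self.day}): {var} min {lo} > max {hi}"
                )
        if not 3 <= self.gcs <= 15:
            raise CohortError(
                f"panel ({self.stay_id}, day {self.day}): GCS {self.gcs} outside 3-15"
            )

    def vmin(self, variable: str) -> float:
        return self.extremes[variable][0]

    def vmax(self, variable: str) -> float:
        return self.extremes[variable][1]


@dataclass
class CohortTable:
    """Validated stays plus their daily worst-value panels."""

    stays: list = field(default_factory=list)
    panels: dict = field(default_factory=dict)  # (stay_id, day) -> DailyWorstPanel

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.stay_id for s in self.stays]
        if len(ids) != len(set(ids)):
            raise ConsistencyError("duplicate stay_id in stays")
        by_id = {s.stay_id: s for s in self.stays}
        days_seen: dict = {}
        for (sid, day), panel in self.panels.items():
            if sid not in by_id:
                raise ConsistencyError(f"panel references unknown stay_id {sid!r}")
            if (panel.stay_id, panel.day) != (sid, day):
                raise ConsistencyError(f"panel key mismatch for ({sid}, {day})")
            days_seen.setdefault(sid, set()).add(day)
        for sid, days in days_seen.items():
            expected = set(range(1, by_id[sid].iculos + 1))
            if days != expected:
                raise ConsistencyError(
                    f"stay {sid}: panel days {sorted(days)} != 1..iculos "
                    f"({by_id[sid].iculos})"
                )

    def stay(self, stay_id: str) -> StayRecord:
        for s in self.stays:
            if s.stay_id == stay_id:
                return s
        raise KeyError(stay_id)

    def panels_for(self, stay_id: str) -> list:
        stay = self.stay(stay_id)
        return [self.panels[(stay_id, d)] for d in range(1, stay.iculos + 1)]

    @property
    def n_stays(self) -> int:
        return len(self.stays)

    def outcomes(self) -> pd.Series:
        """0/1 ICU death indicator indexed by stay_id, in stays order."""
        return pd.Series(
            [1 if s.died else 0 for s in self.stays],
            index=[s.stay_id for s in self.stays],
            name="icu_death",
        )


# ---------------------------------------------------------------------------
# First-admission filtering


def filter_first_admission(stays):
    """Keep only the earliest admission per patient, preserving input order.

    Stays without a ``patient_id`` are treated as unique patients. Two
    admissions of the same patient with identical timestamps are ambiguous
    and rejected.
    """
    earliest: dict = {}
    for s in stays:
        pid = s.patient_id if s.patient_id is not None else f"__stay__{s.stay_id}"
        if pid not in earliest:
            earliest[pid] = s
            continue
        other = earliest[pid]
        t_new = s.admission_datetime or ""
        t_old = other.admission_datetime or ""
        if t_new == t_old:
            raise ConsistencyError(
                f"patient {pid!r}: two admissions with identical timestamp {t_new!r}"
            )
        if t_new < t_old:
            earliest[pid] = s
    kept = set(id(s) for s in earliest.values())
    out = [s for s in stays if id(s) in kept]
    logger.info("first-admission filter: %d stays in, %d retained", len(stays), len(out))
    return out


# ---------------------------------------------------------------------------
# Daily worst-value reduction


def reduce_daily_worst(observations, stay_id=None, day=None, strict=False):
    """Reduce one stay-day's observations to a :class:`DailyWorstPanel`.

    ``observations`` is an iterable of (variable, value) pairs in canonical
    units (flags as 0/1). Continuous variables keep (min, max); urine output
    is summed; flags are OR-ed; GCS takes the daily minimum; ordinal strata
    take the daily maximum. Missing variables are imputed with their normal
    value (and recorded in ``imputed``) unless ``strict`` is set.
    """
    obs = list(observations)
    if not obs:
        raise CohortError("empty observation set for a stay-day")
    seen: dict = {}
    for var, value in obs:
        if var not in vocab.VOCABULARY:
            raise SchemaError(f"unknown variable {var!r}")
        try:
            v = float(value)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric value {value!r} for {var!r}") from exc
        if math.isnan(v):
            raise SchemaError(f"NaN value for {var!r}")
        seen.setdefault(var, []).append(v)
    if stay_id is None:
        stay_id = "?"
    if day is None:
        day = 1

    missing = [
        v
        for v in vocab.CONTINUOUS + vocab.CUMULATIVE + vocab.ORDINAL_MIN + vocab.ORDINAL_MAX
        if v not in seen
    ]
    if strict and missing:
        raise MissingDataError(
            f"stay {stay_id} day {day}: missing variables {missing} in strict mode"
        )

    extremes = {}
    for var in vocab.CONTINUOUS:
        vals = seen.get(var)
        if vals is None:
            normal = float(vocab.NORMAL_VALUES[var])
            extremes[var] = (normal, normal)
        else:
            extremes[var] = (min(vals), max(vals))
    urine = sum(seen["urine_output"]) if "urine_output" in seen else float(
        vocab.NORMAL_VALUES["urine_output"]
    )
    gcs = int(min(seen["gcs"])) if "gcs" in seen else 15
    neuro = int(max(seen["neurologic_state"])) if "neurologic_state" in seen else 0
    cat = (
        int(max(seen["catecholamine_dose_class"]))
        if "catecholamine_dose_class" in seen
        else 0
    )
    flags = {
        f: bool(any(v != 0 for v in seen[f])) if f in seen else False
        for f in vocab.FLAGS
    }
    return DailyWorstPanel(
        stay_id=stay_id,
        day=int(day),
        extremes=extremes,
        urine_output=urine,
        gcs=gcs,
        neurologic_state=neuro,
        catecholamine_dose_class=cat,
        flags=flags,
        imputed=frozenset(missing),
    )


# ---------------------------------------------------------------------------
# CSV I/O

STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "admission_datetime",
    "age",
    "sex",
    "surgery_type",
    "admission_category",
    "outcome",
    "iculos",
    "euroscore_additive",
    "euroscore_logistic",
] + [f"chronic_{f}" for f in vocab.CHRONIC_FLAGS]

OBSERVATION_COLUMNS = ["stay_id", "day", "variable", "value", "unit"]


def _stay_from_row(row) -> StayRecord:
    flags = frozenset(
        f for f in vocab.CHRONIC_FLAGS if int(row.get(f"chronic_{f}", 0) or 0)
    )

    def _opt(col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    return StayRecord(
        stay_id=str(row["stay_id"]),
        patient_id=str(row["patient_id"]) if "patient_id" in row and not pd.isna(row["patient_id"]) else None,
        admission_datetime=str(row["admission_datetime"])
        if "admission_datetime" in row and not pd.isna(row["admission_datetime"])
        else None,
        age=int(row["age"]),
        sex=str(row["sex"]),
        surgery_type=str(row["surgery_type"]),
        admission_category=str(row["admission_category"]),
        outcome=str(row["outcome"]),
        iculos=int(row["iculos"]),
        chronic_health_flags=flags,
        euroscore_additive=_opt("euroscore_additive"),
        euroscore_logistic=_opt("euroscore_logistic"),
    )


def load_cohort(stays_path, observations_path, strict=False, first_admission=True):
    """Load and validate a cohort from the stays and observations CSVs.

    Values are converted to canonical units on load; rows that fail
    validation abort the load with an error naming the offending row.
    """
    stays_df = pd.read_csv(stays_path)
    obs_df = pd.read_csv(observations_path)
    for col in ("stay_id", "age", "sex", "surgery_type", "admission_category",
                "outcome", "iculos"):
        if col not in stays_df.columns:
            raise SchemaError(f"stays file missing column {col!r}")
    for col in OBSERVATION_COLUMNS:
        if col not in obs_df.columns:
            raise SchemaError(f"observations file missing column {col!r}")

    stays = [_stay_from_row(row) for _, row in stays_df.iterrows()]
    if first_admission and any(s.patient_id is not None for s in stays):
        stays = filter_first_admission(stays)
    by_id = {s.stay_id: s for s in stays}

    # canonical-unit conversion with row-level error reporting
    canon = []
    for i, row in obs_df.iterrows():
        sid = str(row["stay_id"])
        var = str(row["variable"])
        if var not in vocab.VOCABULARY:
            raise SchemaError(f"observations row {i}: unknown variable {var!r}")
        if sid not in by_id:
            raise ConsistencyError(
                f"observations row {i}: stay_id {sid!r} not in stays file"
            )
        day = int(row["day"])
        if not 1 <= day <= by_id[sid].iculos:
            raise ConsistencyError(
                f"observations row {i}: day {day} outside 1..iculos "
                f"({by_id[sid].iculos}) for stay {sid}"
            )
        try:
            value = vocab.convert_to_canonical(var, float(row["value"]), str(row["unit"]))
        except ValueError as exc:
            raise UnitError(f"observations row {i}: {exc}") from exc
        canon.append((sid, day, var, value))

    panels = {}
    grouped: dict = {}
    for sid, day, var, value in canon:
        grouped.setdefault((sid, day), []).append((var, value))
    n_imputed = 0
    for stay in stays:
        for day in range(1, stay.iculos + 1):
            key = (stay.stay_id, day)
            if key not in grouped:
                if strict:
                    raise MissingDataError(
                        f"stay {stay.stay_id} day {day}: no observations in strict mode"
                    )
                grouped[key] = [("gcs", 15)]  # fully imputed day
            panel = reduce_daily_worst(
                grouped[key], stay_id=stay.stay_id, day=day, strict=strict
            )
            n_imputed += len(panel.imputed)
            panels[key] = panel
    if n_imputed:
        logger.info("load_cohort: %d variable-days imputed with normal values", n_imputed)
    return CohortTable(stays=stays, panels=panels)


def stays_to_frame(stays) -> pd.DataFrame:
    rows = []
    for s in stays:
        row = {
            "stay_id": s.stay_id,
            "patient_id": s.patient_id,
            "admission_datetime": s.admission_datetime,
            "age": s.age,
            "sex": s.sex,
            "surgery_type": s.surgery_type,
            "admission_category": s.admission_category,
            "outcome": s.outcome,
            "iculos": s.iculos,
            "euroscore_additive": s.euroscore_additive,
            "euroscore_logistic": s.euroscore_logistic,
        }
        for f in vocab.CHRONIC_FLAGS:
            row[f"chronic_{f}"] = int(f in s.chronic_health_flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=STAY_COLUMNS)


def write_cohort(cohort, stays_path, observations_path=None, observations=None):
    """Serialize a cohort's stays (and optionally a long observations frame)."""
    stays_to_frame(cohort.stays).to_csv(stays_path, index=False)
    if observations_path is not None and observations is not None:
        observations.to_csv(observations_path, index=False)
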