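"""Per-day and derivative benchmark of the four scoring systems.

The central object is :class:`ScoreBenchmark`, a model built from a cohort
and its daily score table; ``fit()`` runs, for every requested system and
ICU day (and for the Mean/Max derivatives), the full validation battery —
logistic recalibration with a per-point odds ratio, Hosmer-Lemeshow
calibration on the recalibrated probabilities, ROC discrimination on the
raw points, and overall correct classification — and returns a
:class:`BenchmarkResults` with one :class:`EvaluationRow` per (system, day)
and per (system, derivative).

For day ``d`` the at-risk set is every stay with ICULOS >= d, and the
response is the stay's final ICU outcome (death at any point of the stay),
so early rows use the full cohort and later rows shrink as uncomplicated
stays are discharged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .scoring import SYSTEMS, score_cohort, summarize_scores

logger = logging.getLogger(__name__)

_ROW_COLUMNS = [
    "system",
    "label",
    "n",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
    "occ_pct",
    "hl_chi2",
    "hl_p",
    "auc",
    "auc_ci_low",
    "auc_ci_high",
    "significant_miscalibration",
    "evaluable",
    "note",
]


@dataclass(frozen=True)
class EvaluationRow:
    """One benchmark row: a system on one ICU day or one derivative."""

    system: str
    label: str  # "day 1".."day 6", "mean", "max"
    n: int
    odds_ratio: float = np.nan
    or_ci_low: float = np.nan
    or_ci_high: float = np.nan
    occ_pct: float = np.nan
    hl_chi2: float = np.nan
    hl_p: float = np.nan
    auc: float = np.nan
    auc_ci_low: float = np.nan
    auc_ci_high: float = np.nan
    significant_miscalibration: bool = False
    evaluable: bool = True
    note: str = ""


def _evaluate_one(
    system, label, scores, outcomes, hl_groups, occ_cutoff, auc_ci_method, alpha
) -> EvaluationRow:
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    try:
        fit = stats.fit_score_logistic(x, y)
        hl = stats.hosmer_lemeshow(fit.predicted, y, g=hl_groups)
        roc = stats.roc_auc(x, y, ci_method=auc_ci_method)
        occ_pct = stats.occ(fit.predicted, y, cutoff=occ_cutoff)
    except (stats.DegenerateDataError, stats.SeparationError, ValueError) as exc:
        return EvaluationRow(
            system=system, label=label, n=len(x), evaluable=False, note=str(exc)
        )
    return EvaluationRow(
        system=system,
        label=label,
        n=len(x),
        odds_ratio=fit.odds_ratio,
        or_ci_low=fit.or_ci_low,
        or_ci_high=fit.or_ci_high,
        occ_pct=occ_pct,
        hl_chi2=hl.chi2,
        hl_p=hl.p_value,
        auc=roc.auc,
        auc_ci_low=roc.ci_low,
        auc_ci_high=roc.ci_high,
        significant_miscalibration=bool(hl.p_value < alpha),
    )


def evaluate_per_day(
    cohort,
    score_table: pd.DataFrame,
    system: str,
    days: int = 6,
    hl_groups: int = 10,
    occ_cutoff: float = 0.5,
    auc_ci_method: str = "delong",
    min_at_risk: int = 100,
    alpha: float = 0.05,
) -> list:
    """One :class:`EvaluationRow` per ICU day 1..``days`` for one system.

    Rows whose at-risk set falls below ``min_at_risk`` are returned marked
    unevaluable rather than silently computed on too few subjects.
    """
    outcomes = cohort.outcomes()
    sys_table = score_table[score_table["system"] == system]
    rows = []
    for day in range(1, days + 1):
        day_scores = sys_table[sys_table["day"] == day].set_index("stay_id")["total"]
        at_risk = [s.stay_id for s in cohort.stays if s.iculos >= day]
        label = f"day {day}"
        if len(at_risk) < min_at_risk:
            rows.append(
                EvaluationRow(
                    system=system,
                    label=label,
                    n=len(at_risk),
                    evaluable=False,
                    note=f"at-risk n {len(at_risk)} below minimum {min_at_risk}",
                )
            )
            continue
        x = day_scores.loc[at_risk].to_numpy()
        y = outcomes.loc[at_risk].to_numpy()
        rows.append(
            _evaluate_one(
                system, label, x, y, hl_groups, occ_cutoff, auc_ci_method, alpha
            )
        )
    logger.info(
        "evaluated %s on days 1..%d (n day 1 = %d)", system, days, rows[0].n if rows else 0
    )
    return rows


def evaluate_derivatives(
    cohort,
    summaries: pd.DataFrame,
    system: str,
    hl_groups: int = 10,
    occ_cutoff: float = 0.5,
    auc_ci_method: str = "delong",
    min_at_risk: int = 100,
    alpha: float = 0.05,
) -> list:
    """Mean- and Max-score rows for one system, over all stays."""
    outcomes = cohort.outcomes()
    sys_sum = summaries[summaries["system"] == system].set_index("stay_id")
    rows = []
    for label, column in (("mean", "mean_score"), ("max", "max_score")):
        x = sys_sum.loc[outcomes.index, column].to_numpy(dtype=float)
        y = outcomes.to_numpy()
        if len(x) < min_at_risk:
            rows.append(
                EvaluationRow(
                    system=system,
                    label=label,
                    n=len(x),
                    evaluable=False,
                    note=f"n {len(x)} below minimum {min_at_risk}",
                )
            )
            continue
        rows.append(
            _evaluate_one(
                system, label, x, y, hl_groups, occ_cutoff, auc_ci_method, alpha
            )
        )
    return rows


def rows_to_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=_ROW_COLUMNS)


def render_tables(frame: pd.DataFrame, title: str = "Evaluation") -> str:
    """Plain-text rendering of an evaluation table.

    Hosmer-Lemeshow rows with p < 0.05 (significant miscalibration) are
    flagged with an asterisk; missing values render as blanks.
    """

    def fmt(v, spec):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return ""
        return format(v, spec)

    lines = [title, "=" * len(title)]
    header = (
        f"{'system':<9}{'row':<8}{'n':>6}  {'OR (95% CI)':<22}{'OCC%':>7}"
        f"{'HL chi2':>9}{'HL p':>8}  {'AUC (95% CI)':<20}"
    )
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in frame.iterrows():
        if not r["evaluable"]:
            lines.append(
                f"{r['system']:<9}{r['label']:<8}{r['n']:>6}  "
                f"[not evaluated: {r['note']}]"
            )
            continue
        or_part = (
            f"{fmt(r['odds_ratio'], '.2f')} "
            f"({fmt(r['or_ci_low'], '.2f')}-{fmt(r['or_ci_high'], '.2f')})"
        )
        auc_part = (
            f"{fmt(r['auc'], '.2f')} "
            f"({fmt(r['auc_ci_low'], '.2f')}-{fmt(r['auc_ci_high'], '.2f')})"
        )
        flag = "*" if r["significant_miscalibration"] else " "
        lines.append(
            f"{r['system']:<9}{r['label']:<8}{r['n']:>6}  {or_part:<22}"
            f"{fmt(r['occ_pct'], '.1f'):>7}{fmt(r['hl_chi2'], '.2f'):>9}"
            f"{fmt(r['hl_p'], '.3f'):>7}{flag}  {auc_part:<20}"
        )
    lines.append("")
    lines.append("* Hosmer-Lemeshow p < 0.05: significant miscalibration")
    return "\n".join(lines)


class ScoreBenchmark:
    """Per-day calibration/discrimination benchmark of daily severity scores.

    Parameters
    ----------
    cohort : CohortTable
        Validated stays plus daily worst-value panels.
    score_table : DataFrame, optional
        Tidy daily score table (stay_id, day, system, total, components);
        computed from the cohort when omitted.
    systems : sequence of str
        Subset of {"CASUS", "SOFA", "SAPS2", "APACHE2"}.
    days : int
        Evaluation horizon in ICU days (default 6).
    hl_groups, occ_cutoff, auc_ci_method, min_at_risk, alpha
        Battery settings; see :mod:`icubench.stats`.
    """

    def __init__(
        self,
        cohort,
        score_table: pd.DataFrame | None = None,
        systems=SYSTEMS,
        days: int = 6,
        hl_groups: int = 10,
        occ_cutoff: float = 0.5,
        auc_ci_method: str = "delong",
        min_at_risk: int = 100,
        alpha: float = 0.05,
    ) -> None:
        if not systems:
            raise ValueError("systems subset must be non-empty")
        unknown = set(systems) - set(SYSTEMS)
        if unknown:
            raise ValueError(f"unknown systems {unknown}")
        if days < 1:
            raise ValueError("day horizon must be >= 1")
        self.cohort = cohort
        self.systems = tuple(systems)
        self.days = days
        self.hl_groups = hl_groups
        self.occ_cutoff = occ_cutoff
        self.auc_ci_method = auc_ci_method
        self.min_at_risk = min_at_risk
        self.alpha = alpha
        self.score_table = (
            score_table
            if score_table is not None
            else score_cohort(cohort, systems=self.systems)
        )
        self.summaries = summarize_scores(self.score_table)

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ScoreBenchmark":
        """Build the benchmark scoring the cohort with all four systems."""
        return cls(cohort, **kwargs)

    def fit(self) -> "BenchmarkResults":
        kw = dict(
            hl_groups=self.hl_groups,
            occ_cutoff=self.occ_cutoff,
            auc_ci_method=self.auc_ci_method,
            min_at_risk=self.min_at_risk,
            alpha=self.alpha,
        )
        per_day, derivative = [], []
        for system in self.systems:
            per_day.extend(
                evaluate_per_day(
                    self.cohort, self.score_table, system, days=self.days, **kw
                )
            )
            derivative.extend(
                evaluate_derivatives(self.cohort, self.summaries, system, **kw)
            )
        return BenchmarkResults(self, per_day, derivative)


class BenchmarkResults:
    """Fitted benchmark: per-day and derivative evaluation tables."""

    def __init__(self, model: ScoreBenchmark, per_day_rows, derivative_rows) -> None:
        self.model = model
        self.per_day_rows = list(per_day_rows)
        self.derivative_rows = list(derivative_rows)

    @property
    def per_day(self) -> pd.DataFrame:
        return rows_to_frame(self.per_day_rows)

    @property
    def derivatives(self) -> pd.DataFrame:
        return rows_to_frame(self.derivative_rows)

    def summary(self) -> str:
        return (
            render_tables(self.per_day, title="Per-day evaluation (ICU days 1-%d)" % self.model.days)
            + "\n\n"
            + render_tables(self.derivatives, title="Derivative evaluation (Mean-/Max-score)")
        )

    def to_csv(self, per_day_path, derivatives_path) -> None:
        self.per_day.to_csv(per_day_path, index=False)
        self.derivatives.to_csv(derivatives_path, index=False)
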