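"""Calibration and discrimination statistics for prognostic scores.

The battery mirrors standard external-validation practice for severity
scores: a univariate logistic recalibration of ICU death on score points
(reported as an odds ratio per point with a 95% Wald interval),
Hosmer-Lemeshow goodness-of-fit on the recalibrated probabilities
(decile-of-risk groups, g - 2 degrees of freedom), the area under the ROC
curve with a DeLong (default) or Hanley-McNeil confidence interval, and the
overall correct classification percentage at a probability cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateDataError(ValueError):
    """Inputs cannot support the fit (one outcome class, constant scores...)."""


class SeparationError(RuntimeError):
    """The logistic fit did not converge (e.g. complete separation)."""


@dataclass(frozen=True)
class LogisticFit:
    """Univariate logistic recalibration of outcome on score points."""

    intercept: float
    slope: float
    slope_se: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    predicted: np.ndarray  # per-subject death probability, input order

    def __post_init__(self) -> None:
        if not self.or_ci_low <= self.odds_ratio <= self.or_ci_high:
            raise ValueError("odds-ratio CI does not bracket the point estimate")


@dataclass(frozen=True)
class HLResult:
    """Hosmer-Lemeshow goodness-of-fit over risk-ordered groups."""

    chi2: float
    df: int
    p_value: float
    groups: pd.DataFrame  # columns: n, observed, expected

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class ROCResult:
    """Area under the ROC curve with a 95% confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def _check_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be coded 0/1")
    return y.astype(int)


def fit_score_logistic(scores, outcomes) -> LogisticFit:
    """Maximum-likelihood fit of P(death) = expit(a + b * score).

    Returns the per-point odds ratio exp(b) with its 95% Wald interval and
    the fitted per-subject probabilities for downstream calibration and
    classification statistics.
    """
    x = np.asarray(scores, dtype=float)
    y = _check_binary(outcomes)
    if len(x) != len(y):
        raise ValueError("scores and outcomes differ in length")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise DegenerateDataError("need at least two subjects of each outcome")
    if np.ptp(x) == 0:
        raise DegenerateDataError("scores are all identical")

    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("error", message=".*[Ss]eparation.*")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError, Warning) as exc:
        raise SeparationError(f"logistic fit failed to converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit failed to converge")
    intercept, slope = fit.params
    se = fit.bse[1]
    if not np.isfinite(se) or se > 1e3:
        raise SeparationError("unstable slope standard error (quasi-separation)")
    return LogisticFit(
        intercept=float(intercept),
        slope=float(slope),
        slope_se=float(se),
        odds_ratio=float(np.exp(slope)),
        or_ci_low=float(np.exp(slope - Z95 * se)),
        or_ci_high=float(np.exp(slope + Z95 * se)),
        predicted=np.asarray(fit.predict(design), dtype=float),
    )


def hosmer_lemeshow(predicted, outcomes, g: int = 10) -> HLResult:
    """Hosmer-Lemeshow chi-square over ``g`` equal-size risk groups.

    Subjects are ranked by predicted probability and cut into decile-of-risk
    groups with tied predictions kept in the same group (so fewer than ``g``
    groups can result). chi2 = sum over groups of (O - E)^2 / (E (1 - E/n_g));
    df = n_groups - 2. Groups whose expected deaths are exactly zero are
    merged upward with a warning.
    """
    p = np.asarray(predicted, dtype=float)
    y = _check_binary(outcomes)
    if len(p) != len(y):
        raise ValueError("predicted and outcomes differ in length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    if len(p) < g:
        raise ValueError(f"need at least g={g} subjects for {g} groups")

    try:
        bins = pd.qcut(p, q=g, duplicates="drop")
    except ValueError as exc:  # all predictions identical
        raise DegenerateDataError("cannot form risk groups: no spread") from exc
    table = (
        pd.DataFrame({"bin": bins, "y": y, "p": p})
        .groupby("bin", observed=True)
        .agg(n=("y", "size"), observed=("y", "sum"), expected=("p", "sum"))
        .reset_index(drop=True)
    )
    # merge zero-expectation groups into an adjacent group, preserving order
    rows = table.to_dict("records")
    while len(rows) > 1 and any(r["expected"] == 0 for r in rows):
        i = next(k for k, r in enumerate(rows) if r["expected"] == 0)
        j = i + 1 if i + 1 < len(rows) else i - 1
        warnings.warn("merging a Hosmer-Lemeshow group with zero expected deaths")
        rows[j] = {k: rows[i][k] + rows[j][k] for k in ("n", "observed", "expected")}
        del rows[i]
    table = pd.DataFrame(rows)

    n_g = table["n"].to_numpy(dtype=float)
    obs = table["observed"].to_numpy(dtype=float)
    exp = table["expected"].to_numpy(dtype=float)
    denom = exp * (1.0 - exp / n_g)
    contrib = np.where(denom > 0, (obs - exp) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    chi2 = float(contrib.sum())
    df = max(len(table) - 2, 1)
    return HLResult(
        chi2=chi2, df=df, p_value=float(sps.chi2.sf(chi2, df)), groups=table
    )


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    allv = np.concatenate([pos, neg])
    ranks = sps.rankdata(allv)
    n_pos, n_neg = len(pos), len(neg)
    r_pos = ranks[:n_pos].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    n_pos, n_neg = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    tx = sps.rankdata(allv)[:n_pos]
    ty = sps.rankdata(allv)[n_pos:]
    txx = sps.rankdata(pos)
    tyy = sps.rankdata(neg)
    # structural components: P(X > Y | X = x_i) and P(X > Y | Y = y_j)
    v01 = (tx - txx) / n_neg
    v10 = 1.0 - (ty - tyy) / n_pos
    s01 = np.var(v01, ddof=1) if n_pos > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n_neg > 1 else 0.0
    return s01 / n_pos + s10 / n_neg


def _hanley_mcneil_variance(n_pos: int, n_neg: int, auc: float) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def roc_auc(scores, outcomes, ci_method: str = "delong") -> ROCResult:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2).

    An anti-discriminating score yields AUC < 0.5 and is reported as-is.
    ``ci_method`` is "delong" (default) or "hanley-mcneil"; the 95% interval
    is clipped to [0, 1].
    """
    x = np.asarray(scores, dtype=float)
    y = _check_binary(outcomes)
    pos, neg = x[y == 1], x[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDataError("need at least one subject of each class")
    auc = _mann_whitney_auc(pos, neg)
    if ci_method == "delong":
        var = _delong_variance(pos, neg, auc)
    elif ci_method == "hanley-mcneil":
        var = _hanley_mcneil_variance(len(pos), len(neg), auc)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    half = Z95 * np.sqrt(max(var, 0.0))
    return ROCResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=int(len(pos)),
        n_neg=int(len(neg)),
    )


def occ(predicted, outcomes, cutoff: float = 0.5) -> float:
    """Overall correct classification, in percent.

    A subject is classified as a death when its predicted probability is at
    least ``cutoff``; OCC is the share of subjects whose predicted class
    matches the observed outcome, times 100.
    """
    p = np.asarray(predicted, dtype=float)
    y = _check_binary(outcomes)
    if len(p) == 0:
        raise ValueError("empty input")
    pred_class = (p >= cutoff).astype(int)
    return float((pred_class == y).mean() * 100.0)
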