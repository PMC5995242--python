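"""Kaplan–Meier / log-rank survival comparison and Cox modeling with
backward Wald elimination.

Event-free survival (EFS) is time from diagnosis to any progression;
overall survival (OS) is time to death, censored at last follow-up.
Dichotomized vascular variables are compared by KM curves with the
log-rank test; the joint influence of pre-treatment factors is modeled by
Cox proportional-hazards regression, iteratively excluding the covariate
with the largest Wald p-value ≥ 0.05.  Tied event times use the Efron
partial-likelihood approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood standard errors."""

    time: np.ndarray  # months, event times (step locations)
    survival: np.ndarray
    se: np.ndarray  # Greenwood SE of S(t)
    at_risk: np.ndarray
    survival_at_60_months: float  # percent
    se_at_60_months: float  # percent

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan–Meier estimate from times (months) and event flags (1=event)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    tbl = kmf.event_table
    t = tbl.index.to_numpy(float)
    s = kmf.survival_function_["KM_estimate"].to_numpy()
    # Greenwood: Var[S(t)] = S(t)^2 * cumsum d / (n (n - d))
    d = tbl["observed"].to_numpy(float)
    n = tbl["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n * (n - d) > 0, d / (n * (n - d)), 0.0)
    se = s * np.sqrt(np.cumsum(inc))
    curve = KMCurve(
        time=t,
        survival=s,
        se=se,
        at_risk=n,
        survival_at_60_months=0.0,
        se_at_60_months=0.0,
    )
    idx = np.searchsorted(t, 60.0, side="right") - 1
    s60 = 1.0 if idx < 0 else float(s[idx])
    se60 = 0.0 if idx < 0 else float(se[idx])
    curve.survival_at_60_months = 100.0 * s60
    curve.se_at_60_months = 100.0 * se60
    return curve


@dataclass
class LogrankResult:
    chi2: float
    p: float


def logrank_test(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> LogrankResult:
    """One-degree log-rank test between two groups (binary factor)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g = np.asarray(groups, bool)
    if event.sum() == 0:
        raise ValueError("no events in either group")
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(time[~g], time[g], event[~g], event[g])
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value))


@dataclass(frozen=True)
class CoxCoefficient:
    covariate: str
    coef: float  # log-hazard
    hr: float  # hazard ratio exp(coef)
    ci95: tuple[float, float]
    p: float
    retained: bool
    note: str = ""


@dataclass
class CoxFit:
    coefficients: list[CoxCoefficient]
    n: int
    n_events: int

    @property
    def retained(self) -> dict[str, CoxCoefficient]:
        return {c.covariate: c for c in self.coefficients if c.retained}

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": c.covariate,
                    "coef": c.coef,
                    "HR": c.hr,
                    "ci_low": c.ci95[0],
                    "ci_high": c.ci95[1],
                    "p": c.p,
                    "retained": c.retained,
                    "note": c.note,
                }
                for c in self.coefficients
            ]
        )


def cox_backward_wald(
    time: np.ndarray,
    event: np.ndarray,
    covariates: pd.DataFrame,
    drop_p: float = 0.05,
) -> CoxFit:
    """Cox regression with backward elimination by Wald p-value.

    Starting from all covariates, the one with the largest Wald p ≥
    ``drop_p`` is removed and the model refit, until every remaining
    covariate is significant.  Dropped covariates are reported with
    ``retained=False`` and the exclusion note.  Covariates with monotone
    likelihood (separation-like degeneracy, detected as exploding |coef|)
    are flagged and removed first.
    """
    df = covariates.astype(float).copy()
    df["_time"] = np.asarray(time, float)
    df["_event"] = np.asarray(event, int)
    if df["_event"].sum() < 2:
        raise ValueError("need at least 2 events")

    results: dict[str, CoxCoefficient] = {}
    cols = list(covariates.columns)
    while cols:
        cph = CoxPHFitter()
        cph.fit(df[cols + ["_time", "_event"]], duration_col="_time", event_col="_event")
        summ = cph.summary
        flagged = [c for c in cols if abs(float(summ.loc[c, "coef"])) > 15]
        if flagged:
            c = flagged[0]
            results[c] = CoxCoefficient(
                c, float(summ.loc[c, "coef"]), float(np.exp(summ.loc[c, "coef"])),
                (np.nan, np.nan), float(summ.loc[c, "p"]), False,
                note="monotone likelihood / separation",
            )
            cols.remove(c)
            continue
        worst = summ["p"].idxmax()
        if float(summ.loc[worst, "p"]) >= drop_p and len(cols) > 0:
            results[worst] = CoxCoefficient(
                worst,
                float(summ.loc[worst, "coef"]),
                float(summ.loc[worst, "exp(coef)"]),
                (
                    float(summ.loc[worst, "exp(coef) lower 95%"]),
                    float(summ.loc[worst, "exp(coef) upper 95%"]),
                ),
                float(summ.loc[worst, "p"]),
                False,
                note="excluded from the equation (p >= 0.05)",
            )
            cols.remove(worst)
            continue
        for c in cols:
            results[c] = CoxCoefficient(
                c,
                float(summ.loc[c, "coef"]),
                float(summ.loc[c, "exp(coef)"]),
                (
                    float(summ.loc[c, "exp(coef) lower 95%"]),
                    float(summ.loc[c, "exp(coef) upper 95%"]),
                ),
                float(summ.loc[c, "p"]),
                True,
            )
        break

    ordered = [results[c] for c in covariates.columns if c in results]
    return CoxFit(ordered, n=len(df), n_events=int(df["_event"].sum()))


def hr_from_ci(ci_low: float, ci_high: float) -> float:
    """Point hazard ratio implied by a symmetric Wald 95% CI.

    On the log scale a Wald interval is symmetric around the estimate, so
    the point HR is the geometric mean of the CI bounds.  Useful as an
    internal-consistency check on reported (HR, CI) triples.
    """
    if not (0 < ci_low <= ci_high):
        raise ValueError("require 0 < ci_low <= ci_high")
    return float(np.exp(0.5 * (np.log(ci_low) + np.log(ci_high))))
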