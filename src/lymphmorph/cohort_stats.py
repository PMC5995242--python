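"""Cohort-level inference: dichotomization, group contrasts, logistic risk
modeling with backward elimination, odds-product risk scoring, and the
Rice-rule histogram / excess-kurtosis heterogeneity machinery.

Continuous morphometric variables are dichotomized at their median (low =
reference category).  Group contrasts use the two-sided Mann–Whitney test
(exact for small groups).  Risk modeling is binary logistic regression with
backward elimination by likelihood-ratio removal tests; the fitted model is
summarised as the multiplicative odds equation

    odds multiplier = Π  Exp(B_j) ** [indicator_j is high]

Distributional heterogeneity is assessed per variable with Rice-rule
normalized histograms and the excess kurtosis G2 = m4/m2² − 3, standardised
by SEK = √(24/n); |Zg2| = |G2/SEK| > 2 flags departure from normality at
the 95% level (leptokurtic when positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


# ---------------------------------------------------------------------------
# dichotomization and contrasts


class Dichotomized(NamedTuple):
    labels: np.ndarray  # bool, True = above the median ("high")
    median: float


def dichotomize_at_median(values: Sequence[float]) -> Dichotomized:
    """Binary high/low labels at the median (high iff value > median).

    The median is computed over finite values only; with an all-equal
    vector nothing exceeds the median, so every label is low.
    """
    arr = np.asarray(values, float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to dichotomize")
    med = float(np.median(finite))
    return Dichotomized(labels=arr > med, median=med)


class GroupContrast(NamedTuple):
    p: float
    direction: str  # "up" (adverse group higher), "down", or "none"
    statistic: float
    n_ref: int
    n_adverse: int


def compare_groups(values: Sequence[float], groups: Sequence[bool]) -> GroupContrast:
    """Two-sided Mann–Whitney contrast of a variable between two groups.

    ``groups`` is a binary factor (True = adverse group).  The test is
    exact when both groups have ≤ 8 observations and no ties, otherwise the
    tie-corrected normal approximation.  ``direction`` reports the sign of
    the adverse-minus-reference median difference.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups, bool)
    x, y = v[~g], v[g]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(v)) < len(v)
    method = "exact" if (max(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    dmed = float(np.median(y) - np.median(x))
    direction = "none" if dmed == 0 else ("up" if dmed > 0 else "down")
    return GroupContrast(
        p=float(res.pvalue),
        direction=direction,
        statistic=float(res.statistic),
        n_ref=len(x),
        n_adverse=len(y),
    )


def contrast_table(
    features: pd.DataFrame,
    factors: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Variable × factor contrast grid (p-value and direction arrows).

    Cells show ``p ↑``/``p ↓`` when significant at ``alpha``, else ``−``;
    each factor column of ``factors`` is a binary adverse indicator aligned
    with the rows of ``features``.
    """
    rows = []
    for var in features.columns:
        row = {"variable": var}
        for fac in factors.columns:
            sub = pd.concat([features[var], factors[fac]], axis=1).dropna()
            try:
                c = compare_groups(sub[var], sub[fac].astype(bool))
            except ValueError:
                row[fac] = "-"
                continue
            if c.p < alpha and c.direction != "none":
                arrow = "↑" if c.direction == "up" else "↓"
                row[fac] = f"{c.p:.3f} {arrow}"
            else:
                row[fac] = "-"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic risk model


def exp_coefficient(B: float) -> float:
    """Odds ratio e^B for a log-odds coefficient."""
    if not np.isfinite(B):
        raise ValueError("B must be finite")
    return float(np.exp(B))


def wald_statistic(B: float, SE: float) -> tuple[float, float]:
    """Wald χ² statistic (B/SE)² and its 1-df upper-tail p-value."""
    if SE <= 0:
        raise ValueError("SE must be positive")
    w = (B / SE) ** 2
    return float(w), float(stats.chi2.sf(w, df=1))


@dataclass(frozen=True)
class RiskCoefficient:
    """One row of the logistic risk table (reference category = low)."""

    variable: str
    B: float
    SE: float
    wald: float
    p: float
    exp_b: float
    estimable: bool = True

    @classmethod
    def from_fit(cls, variable: str, B: float, SE: float) -> "RiskCoefficient":
        w, p = wald_statistic(B, SE)
        return cls(variable, float(B), float(SE), w, p, exp_coefficient(B))


@dataclass
class RiskModel:
    coefficients: list[RiskCoefficient]
    eliminated: list[str]
    intercept: float
    n: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": c.variable,
                    "B": c.B,
                    "SE": c.SE,
                    "Wald": c.wald,
                    "p": c.p,
                    "ExpB": c.exp_b,
                    "estimable": c.estimable,
                }
                for c in self.coefficients
            ]
        )


def _logit_fit(X: pd.DataFrame, y: np.ndarray):
    # IRLS with a pseudo-inverse step: tolerant of near-collinear indicator
    # sets, which backward elimination then prunes
    model = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                   family=sm.families.Binomial())
    return model.fit(maxiter=200)


def fit_risk_model(
    features: pd.DataFrame,
    outcome: Sequence[int],
    stay_p: float = 0.10,
) -> RiskModel:
    """Backward-elimination logistic regression of a binary outcome.

    ``features`` holds 0/1 indicators (1 = above the median); the low
    group is the reference category.  Starting from the full model, the
    term with the largest likelihood-ratio removal p-value is dropped while
    that p-value is ≥ ``stay_p``; with nothing significant an
    intercept-only model is returned.  Quasi-separated coefficients
    (|B| explodes) are flagged non-estimable.
    """
    y = np.asarray(outcome, int)
    X = features.astype(float).copy()
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more samples than features")
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"constant column {col!r} after dichotomization")

    eliminated: list[str] = []
    while len(X.columns) > 0:
        full = _logit_fit(X, y)
        # LR removal p per term
        removal = {}
        for col in X.columns:
            red = _logit_fit(X.drop(columns=[col]), y)
            lr = 2.0 * (full.llf - red.llf)
            removal[col] = float(stats.chi2.sf(max(lr, 0.0), df=1))
        worst = max(removal, key=removal.get)
        if removal[worst] >= stay_p:
            eliminated.append(worst)
            X = X.drop(columns=[worst])
        else:
            break

    if len(X.columns) == 0:
        fit = _logit_fit(pd.DataFrame(index=features.index), y)
        return RiskModel([], eliminated, float(fit.params.iloc[0]), len(y))

    fit = _logit_fit(X, y)
    coeffs = []
    for col in X.columns:
        B = float(fit.params[col])
        SE = float(fit.bse[col])
        c = RiskCoefficient.from_fit(col, B, SE)
        if abs(B) > 15 or SE > 50:  # quasi-separation
            c = RiskCoefficient(col, B, SE, c.wald, c.p, c.exp_b, estimable=False)
        coeffs.append(c)
    return RiskModel(coeffs, eliminated, float(fit.params["const"]), len(y))


def risk_odds_product(
    indicators: Mapping[str, object],
    model: Iterable[RiskCoefficient],
) -> float:
    """Multiplicative odds change for one sample's high/low profile.

    Every model variable whose indicator is high contributes its Exp(B)
    factor; low (or absent) indicators contribute 1.  Indicator values may
    be booleans or the strings ``"high"``/``"low"``.
    """

    def is_high(v) -> bool:
        if isinstance(v, str):
            if v not in ("high", "low"):
                raise ValueError(f"indicator must be 'high' or 'low', got {v!r}")
            return v == "high"
        return bool(v)

    product = 1.0
    for coef in model:
        if not np.isfinite(coef.exp_b):
            raise ValueError(f"non-finite coefficient for {coef.variable!r}")
        if is_high(indicators.get(coef.variable, False)):
            product *= coef.exp_b
    return product


# ---------------------------------------------------------------------------
# heterogeneity: Rice-rule histograms and excess kurtosis


def rice_bins(N: int) -> int:
    """Rice's rule bin count, ⌈2·N^(1/3)⌉."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return int(math.ceil(2.0 * N ** (1.0 / 3.0) - 1e-12))


@dataclass(frozen=True)
class HistogramSpec:
    n_bins: int
    bin_edges: np.ndarray
    normalized_counts: np.ndarray  # fractions summing to 1
    zeros_discarded: bool
    n: int


def normalized_histogram(
    values: Sequence[float], discard_zeros: bool = False
) -> HistogramSpec:
    """Rice-rule histogram with counts normalised to sum to 1.

    With ``discard_zeros`` (used for relative density / relative %SA, where
    zero means no vessel at all), zeros are dropped before the bin count is
    derived from the remaining N.
    """
    arr = np.asarray(values, float)
    arr = arr[np.isfinite(arr)]
    if discard_zeros:
        arr = arr[arr != 0]
    if arr.size == 0:
        raise ValueError("no values left to histogram")
    k = rice_bins(arr.size)
    counts, edges = np.histogram(arr, bins=k)
    return HistogramSpec(
        n_bins=k,
        bin_edges=edges,
        normalized_counts=counts / counts.sum(),
        zeros_discarded=discard_zeros,
        n=int(arr.size),
    )


@dataclass(frozen=True)
class KurtosisReport:
    variable: str
    n: int
    G2: float  # excess kurtosis m4/m2^2 - 3 (population-normalised moments)
    SEK: float  # sqrt(24/n)
    Zg2: float
    verdict: str  # leptokurtic / normal / platykurtic


def excess_kurtosis(values: Sequence[float], variable: str = "") -> KurtosisReport:
    """Excess kurtosis G2 with its standard error and normality verdict.

    G2 is the plain fourth standardized central moment minus 3; SEK is
    √(24/n).  Zg2 = G2/SEK > 2 ⇒ leptokurtic, < −2 ⇒ platykurtic, otherwise
    consistent with normality at the 95% level.
    """
    arr = np.asarray(values, float)
    arr = arr[np.isfinite(arr)]
    n = arr.size
    if n < 4:
        raise ValueError("need at least 4 values")
    if np.var(arr) == 0:
        raise ValueError("zero variance: kurtosis undefined")
    g2 = float(stats.kurtosis(arr, fisher=True, bias=True))
    sek = math.sqrt(24.0 / n)
    z = g2 / sek
    verdict = "leptokurtic" if z > 2 else ("platykurtic" if z < -2 else "normal")
    return KurtosisReport(variable=variable, n=n, G2=g2, SEK=sek, Zg2=z, verdict=verdict)


def kurtosis_table(
    features: pd.DataFrame, discard_zeros_for: Sequence[str] = ()
) -> pd.DataFrame:
    """Per-variable histogram + kurtosis report over a feature table."""
    rows = []
    for var in features.columns:
        vals = features[var].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if var in discard_zeros_for:
            vals = vals[vals != 0]
        if vals.size < 4 or np.var(vals) == 0:
            continue
        rep = excess_kurtosis(vals, variable=var)
        rows.append(
            {
                "variable": var,
                "n": rep.n,
                "n_bins": rice_bins(rep.n),
                "G2": rep.G2,
                "SEK": rep.SEK,
                "Zg2": rep.Zg2,
                "verdict": rep.verdict,
                "zeros_discarded": var in discard_zeros_for,
            }
        )
    return pd.DataFrame(rows)
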