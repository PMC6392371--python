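"""Life-history derivations: growth curves, age at maturity, group summaries,
ANOVA contrasts and growth--environment correlations.

A fitted growth-rate model plus a hatchling size ``L0`` determines an
integrated growth curve; inverting the curve at the sex-specific SVL at
sexual maturity yields the age at maturity in days.  Growth rates are
further summarised per sex x age-class x season x year cell (mean +/- SE),
contrasted with fixed-effects ANOVA, and correlated (Pearson) with monthly
environmental covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NonIdentifiableError
from .fit import GrowthRateResults
from .models import GrowthCurve, GrowthParams

__all__ = [
    "MaturityRule",
    "DEFAULT_MATURITY_RULES",
    "AnovaResult",
    "EnvCorrelation",
    "build_growth_curve",
    "age_at_maturity",
    "summarize_groups",
    "anova_growth",
    "correlate_growth_env",
    "monthly_growth_series",
]

FACTOR_COLUMNS = {
    "sex": "sex",
    "season": "season",
    "year": "year",
    "age_class": "age_class",
}


@dataclass(frozen=True)
class MaturityRule:
    """Sex-specific SVL (mm) at which sexual maturity is attained."""

    sex: str
    svl_at_maturity: float


#: minimum SVL at sexual maturity: 35 mm for males, 37 mm for females
DEFAULT_MATURITY_RULES = {
    "male": MaturityRule("male", 35.0),
    "female": MaturityRule("female", 37.0),
}


@dataclass(frozen=True)
class AnovaResult:
    """One factor's fixed-effects ANOVA contrast on growth rate."""

    factors: tuple[str, ...]
    factor: str
    f_stat: float
    df: tuple[float, float]
    p_value: float
    group_means: dict


@dataclass(frozen=True)
class EnvCorrelation:
    """Pearson correlation of monthly growth with one environmental covariate."""

    covariate: str
    coefficient: float
    p_value: float
    n: int
    year: int | None = None


def build_growth_curve(fit: GrowthRateResults | GrowthParams, l0: float, family=None) -> GrowthCurve:
    """Anchor a fitted model at hatchling size ``l0`` to get a growth curve.

    Accepts either a fit result (family taken from it) or bare parameters
    plus an explicit ``family``.
    """
    if isinstance(fit, GrowthRateResults):
        if not fit.converged:
            raise ValueError("refusing to build a curve from an unconverged fit")
        params, family = fit.params, fit.family
    else:
        if family is None:
            raise ValueError("family is required when passing bare parameters")
        params = fit
    return GrowthCurve(family=family, params=params, l0=l0)


def age_at_maturity(curve: GrowthCurve, rule: MaturityRule | float) -> float:
    """Age in days at which the growth curve reaches the maturity SVL."""
    svl = rule.svl_at_maturity if isinstance(rule, MaturityRule) else float(rule)
    return curve.time_to_length(svl)


def summarize_groups(
    intervals: pd.DataFrame,
    by: list[str] = ("sex", "age_class", "season", "year"),
) -> pd.DataFrame:
    """Per-cell growth-rate summary: n, mean and standard error.

    Cells with no observations are omitted; singleton cells report SE 0.
    """
    by = list(by)
    unknown = [f for f in by if f not in FACTOR_COLUMNS]
    if unknown:
        raise ValueError(f"unknown factor(s): {', '.join(unknown)}")
    if intervals.empty:
        return pd.DataFrame(columns=by + ["n", "mean_gr", "se_gr"])
    grouped = intervals.groupby(by, observed=True)["gr_mm_per_day"]
    out = grouped.agg(
        n="size",
        mean_gr="mean",
        se_gr=lambda g: (g.std(ddof=1) / np.sqrt(len(g))) if len(g) > 1 else 0.0,
    ).reset_index()
    return out


def anova_growth(intervals: pd.DataFrame, factors: list[str]) -> list[AnovaResult]:
    """Fixed-effects ANOVA of growth rate on one or more factors.

    A single factor uses the classical one-way F test; several factors fit an
    additive fixed-effects linear model with type-I (sequential) sums of
    squares, returning one result per factor.  Raises when any factor has a
    single level or the response is constant (F undefined).
    """
    factors = list(factors)
    unknown = [f for f in factors if f not in FACTOR_COLUMNS]
    if unknown:
        raise ValueError(f"unknown factor(s): {', '.join(unknown)}")
    if not factors:
        raise ValueError("at least one factor required")
    gr = intervals["gr_mm_per_day"].to_numpy(dtype=float)
    if np.ptp(gr) == 0.0:
        raise NonIdentifiableError("growth rates are constant; F undefined")
    for f in factors:
        levels = intervals[f].nunique()
        if levels < 2:
            raise ValueError(f"factor {f!r} has {levels} level(s); need >= 2")

    means = {
        f: intervals.groupby(f, observed=True)["gr_mm_per_day"].mean().to_dict()
        for f in factors
    }
    if len(factors) == 1:
        f = factors[0]
        groups = [g.to_numpy() for _, g in intervals.groupby(f, observed=True)["gr_mm_per_day"]]
        if any(len(g) < 2 for g in groups):
            raise ValueError("each group needs at least 2 observations")
        stat = stats.f_oneway(*groups)
        k, n = len(groups), len(gr)
        return [
            AnovaResult(
                factors=(f,),
                factor=f,
                f_stat=float(stat.statistic),
                df=(k - 1, n - k),
                p_value=float(stat.pvalue),
                group_means=means[f],
            )
        ]

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = intervals[factors + ["gr_mm_per_day"]].rename(columns={"gr_mm_per_day": "gr"})
    formula = "gr ~ " + " + ".join(f"C({f})" for f in factors)
    table = sm.stats.anova_lm(smf.ols(formula, data=data).fit(), typ=1)
    resid_df = float(table.loc["Residual", "df"])
    out = []
    for f in factors:
        row = table.loc[f"C({f})"]
        out.append(
            AnovaResult(
                factors=tuple(factors),
                factor=f,
                f_stat=float(row["F"]),
                df=(float(row["df"]), resid_df),
                p_value=float(row["PR(>F)"]),
                group_means=means[f],
            )
        )
    return out


def monthly_growth_series(intervals: pd.DataFrame) -> pd.DataFrame:
    """Mean growth rate per calendar month, keyed by the interval midpoint.

    Returns a DataFrame with year, month, n and mean_gr, sorted in time.
    """
    if "mid_date" not in intervals.columns:
        raise ValueError("intervals must carry a mid_date column")
    mid = pd.to_datetime(intervals["mid_date"])
    frame = pd.DataFrame(
        {"year": mid.dt.year, "month": mid.dt.month, "gr": intervals["gr_mm_per_day"]}
    )
    out = (
        frame.groupby(["year", "month"])["gr"]
        .agg(n="size", mean_gr="mean")
        .reset_index()
        .sort_values(["year", "month"], ignore_index=True)
    )
    return out


def correlate_growth_env(
    gr_series,
    covariate_series,
    covariate: str = "covariate",
    year: int | None = None,
) -> EnvCorrelation:
    """Pearson correlation (two-sided p) of aligned monthly series."""
    x = np.asarray(gr_series, dtype=float)
    y = np.asarray(covariate_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be aligned 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 aligned months")
    if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        raise NonIdentifiableError("zero-variance series; correlation undefined")
    res = stats.pearsonr(x, y)
    return EnvCorrelation(
        covariate=covariate,
        coefficient=float(res.statistic),
        p_value=float(res.pvalue),
        n=x.size,
        year=year,
    )
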