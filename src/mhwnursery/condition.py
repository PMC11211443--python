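"""Abundance and body-condition summaries.

Catch per unit effort (fish per seine haul), hepatosomatic index, pooled
log-linear length-weight condition residuals, yearly minimum-length
models, and July-to-August percent-change summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LWFit",
    "cpue",
    "hsi",
    "lw_condition",
    "min_length_by_year",
    "percent_change_july_august",
]


def cpue(hauls: pd.DataFrame, by: list[str] = ("year", "month")) -> pd.DataFrame:
    """Mean catch per haul with SE over hauls, per stratum.

    ``hauls`` columns: year, month, site, haul_id, n_cod.  Strata with a
    single haul get a missing SE.
    """
    if (hauls["n_cod"] < 0).any():
        raise ValueError("negative haul count")
    g = hauls.groupby(list(by))["n_cod"]
    out = g.agg(cpue="mean", n_hauls="count", sd="std")
    out["se"] = out["sd"] / np.sqrt(out["n_hauls"])
    return out.drop(columns="sd").reset_index()


def hsi(liver_g: float, body_g: float) -> float:
    """Hepatosomatic index: liver mass as a percentage of whole-body mass."""
    if body_g <= 0:
        raise ValueError("body mass must be positive")
    if liver_g < 0 or liver_g >= body_g:
        raise ValueError(f"liver mass {liver_g} not in [0, body {body_g})")
    return 100.0 * liver_g / body_g


@dataclass
class LWFit:
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    r2_adj: float
    residuals: pd.Series  # fish_id -> ln-scale residual


def lw_condition(fish: pd.DataFrame) -> LWFit:
    """OLS of ln(mass g) on ln(standard length mm), pooled across years.

    Returns coefficients with SEs, adjusted R-squared, and the per-fish
    ln-scale residuals used as length-weight condition indices.
    """
    if len(fish) < 3:
        raise ValueError("need at least 3 fish for a length-weight fit")
    if (fish["sl_mm"] <= 0).any() or (fish["mass_g"] <= 0).any():
        raise ValueError("lengths and masses must be positive")
    x = np.log(fish["sl_mm"].to_numpy(float))
    y = np.log(fish["mass_g"].to_numpy(float))
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - 2
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    return LWFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        intercept_se=float(np.sqrt(cov[0, 0])),
        slope_se=float(np.sqrt(cov[1, 1])),
        r2_adj=r2_adj,
        residuals=pd.Series(resid, index=fish["fish_id"].to_numpy()),
    )


def min_length_by_year(fish: pd.DataFrame, month: int | str) -> dict:
    """Yearly minimum standard length for one month and an OLS of the
    minima on heatwave class (reference level = first class by order
    Before < Between < Heatwave present)."""
    sub = fish[fish["month"] == month]
    if sub.empty:
        raise ValueError(f"no fish in month {month!r}")
    minima = sub.groupby(["year", "class"])["sl_mm"].min().reset_index()
    order = [c for c in ("Before", "Between", "Heatwave") if c in set(minima["class"])]
    means = minima.groupby("class")["sl_mm"].mean().reindex(order)
    result = {"minima": minima, "class_means": means, "saturated": False}
    counts = minima["class"].value_counts()
    if (counts <= 1).all() or len(order) < 2:
        result["saturated"] = True
        return result
    # OLS with class dummies; overall F-test p-value for a class effect
    y = minima["sl_mm"].to_numpy(float)
    dummies = pd.get_dummies(
        pd.Categorical(minima["class"], categories=order), drop_first=True
    ).to_numpy(float)
    X = np.column_stack([np.ones(len(y)), dummies])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(((y - X @ beta) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    df1, df2 = X.shape[1] - 1, len(y) - X.shape[1]
    if df2 <= 0 or rss1 <= 0:
        result["saturated"] = True
        return result
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    result["coefficients"] = dict(zip(["intercept"] + order[1:], beta))
    result["f_pvalue"] = float(stats.f.sf(f, df1, df2))
    return result


def percent_change_july_august(
    fish: pd.DataFrame,
    metric: str = "sl_mm",
    july=7,
    august=8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-year July-to-August percent change in the mean of ``metric``,
    then class-level mean +/- SE across years.

    Years missing either month are excluded.  The per-year-then-average
    order is what produces the class-level +/- values.
    """
    means = fish.groupby(["year", "class", "month"])[metric].mean().unstack("month")
    if july not in means.columns or august not in means.columns:
        raise ValueError("need both July and August samples")
    means = means.dropna(subset=[july, august])
    per_year = (
        100.0 * (means[august] - means[july]) / means[july]
    ).rename("pct_change").reset_index()
    g = per_year.groupby("class")["pct_change"]
    by_class = g.agg(mean="mean", n_years="count", sd="std")
    by_class["se"] = by_class["sd"] / np.sqrt(by_class["n_years"])
    return per_year, by_class.drop(columns="sd").reset_index()
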