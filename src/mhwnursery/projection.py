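"""Forward size projection and survival-quantile analysis.

July fish are projected to expected August sizes by compounding the
year's mean July relative growth over the inter-sampling interval
(default 40 days).  The survival quantile q* is the largest fraction q
such that the mean of the top-q predicted sizes still reaches the
observed August mean; the simulated-population variant repeats the
search on large truncated-normal populations with field-sized draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "predict_august_sizes",
    "compare_predicted_observed",
    "top_q_mean_curve",
    "survival_quantile_search",
    "normal_top_q_mean",
    "simulate_populations",
]


def predict_august_sizes(
    july_fish: pd.DataFrame,
    growth_by_year: pd.Series | dict,
    days: int | pd.Series | dict = 40,
    mode: str = "multiplicative",
) -> pd.DataFrame:
    """Predicted August length per July fish.

    ``growth_by_year`` maps year to mean July relative growth (per day);
    ``days`` is the inter-sampling interval, scalar or per year.
    Multiplicative mode compounds L * (1+g)^d; additive mode adds
    d * g * mean July length for that year.  Years without a growth
    summary are skipped with a warning.
    """
    growth = pd.Series(growth_by_year, dtype=float)
    days_s = (
        pd.Series(days, dtype=float)
        if isinstance(days, (pd.Series, dict))
        else pd.Series({y: float(days) for y in growth.index})
    )
    out = []
    for year, grp in july_fish.groupby("year"):
        if year not in growth.index or pd.isna(growth.get(year)):
            import warnings

            warnings.warn(f"no July growth summary for {year}; skipped", stacklevel=2)
            continue
        g, d = float(growth[year]), float(days_s[year])
        L = grp["sl_mm"].to_numpy(float)
        if mode == "multiplicative":
            pred = L * (1.0 + g) ** d
        elif mode == "additive":
            pred = L + d * g * L.mean()
        else:
            raise ValueError(f"unknown projection mode {mode!r}")
        block = grp.copy()
        block["predicted_sl_mm"] = pred
        out.append(block)
    if not out:
        raise ValueError("no year could be projected")
    return pd.concat(out, ignore_index=True)


def compare_predicted_observed(
    predicted: pd.DataFrame, august_fish: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-year percent gap between observed and predicted August means,
    then class-level mean +/- SE across years."""
    pred_means = predicted.groupby(["year", "class"])["predicted_sl_mm"].mean()
    obs_means = august_fish.groupby(["year", "class"])["sl_mm"].mean()
    joined = pd.concat(
        [pred_means.rename("predicted"), obs_means.rename("observed")], axis=1
    ).dropna()
    joined["pct_gap"] = 100.0 * (joined["observed"] - joined["predicted"]) / joined["predicted"]
    per_year = joined.reset_index()
    g = per_year.groupby("class")["pct_gap"]
    by_class = g.agg(mean="mean", n_years="count", sd="std")
    by_class["se"] = by_class["sd"] / np.sqrt(by_class["n_years"])
    return per_year, by_class.drop(columns="sd").reset_index()


def top_q_mean_curve(values: np.ndarray) -> pd.DataFrame:
    """Mean of the largest k values for every k (q = k/n); monotone
    non-increasing in q."""
    v = np.sort(np.asarray(values, float))[::-1]
    n = len(v)
    means = np.cumsum(v) / np.arange(1, n + 1)
    if np.any(np.diff(means) > 1e-9):
        raise AssertionError("top-q mean curve must be non-increasing")
    return pd.DataFrame({"q": np.arange(1, n + 1) / n, "top_q_mean": means})


@dataclass
class QuantileSearchResult:
    q_star: float | None
    top_q_mean: float | None
    curve: pd.DataFrame
    observed_mean: float
    ci_covers: bool | None = None
    landmarks: dict[float, float] = field(default_factory=dict)


def survival_quantile_search(
    predicted_sizes: np.ndarray,
    observed_mean: float,
    observed_ci: tuple[float, float] | None = None,
    landmarks: tuple[float, ...] = (0.15, 0.25),
) -> QuantileSearchResult:
    """Largest q whose top-q predicted mean reaches the observed mean.

    Searched on the empirical grid q = k/n with ties broken toward larger
    q; returns the full curve, the top-q mean at q*, whether the observed
    95% CI covers it, and top-q means at the landmark quantiles.
    """
    v = np.asarray(predicted_sizes, float)
    if len(v) == 0:
        raise ValueError("predicted sizes are empty")
    curve = top_q_mean_curve(v)
    ok = curve["top_q_mean"].to_numpy() >= observed_mean
    if not ok.any():
        q_star, top_mean = None, None
    else:
        k = int(np.flatnonzero(ok).max())
        q_star = float(curve["q"].iloc[k])
        top_mean = float(curve["top_q_mean"].iloc[k])
    covers = None
    if observed_ci is not None and top_mean is not None:
        covers = bool(observed_ci[0] <= top_mean <= observed_ci[1])
    lm = {}
    for q in landmarks:
        k = max(int(np.ceil(q * len(v))), 1)
        lm[q] = float(curve["top_q_mean"].iloc[k - 1])
    return QuantileSearchResult(
        q_star=q_star,
        top_q_mean=top_mean,
        curve=curve,
        observed_mean=float(observed_mean),
        ci_covers=covers,
        landmarks=lm,
    )


def normal_top_q_mean(mu: float, sigma: float, q: float) -> float:
    """Closed form for the mean of the top-q fraction of a normal
    population: mu + sigma * phi(z_q) / q with z_q = Phi^-1(1-q)."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    z = stats.norm.ppf(1.0 - q)
    return mu + sigma * stats.norm.pdf(z) / q


def simulate_populations(
    predicted_mean: float,
    predicted_sd: float,
    observed_mean: float,
    observed_sd: float,
    n_population: int = 10_000,
    field_sample_size: int = 50,
    floor_mm: float = 20.0,
    seed: int = 0,
) -> dict:
    """Simulated-population survival-quantile analysis.

    Draws truncated-normal populations of predicted and observed sizes,
    takes field-sized random samples, and runs the quantile search of the
    predicted population against the sampled observed mean.
    """
    if predicted_sd <= 0 or observed_sd <= 0:
        raise ValueError("population sd must be positive")
    if n_population < field_sample_size:
        raise ValueError("population smaller than the field sample")
    rng = np.random.default_rng(seed)

    def trunc_normal(mu, sd, n):
        a = (floor_mm - mu) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n,
                                   random_state=rng)

    pred_pop = trunc_normal(predicted_mean, predicted_sd, n_population)
    obs_pop = trunc_normal(observed_mean, observed_sd, n_population)
    obs_sample = rng.choice(obs_pop, size=field_sample_size, replace=False)
    pred_sample = rng.choice(pred_pop, size=field_sample_size, replace=False)
    obs_mean = float(obs_sample.mean())
    obs_se = float(obs_sample.std(ddof=1) / np.sqrt(field_sample_size))
    search = survival_quantile_search(
        pred_pop, obs_mean, observed_ci=(obs_mean - 1.96 * obs_se,
                                         obs_mean + 1.96 * obs_se)
    )
    return {
        "predicted_population_mean": float(pred_pop.mean()),
        "observed_population_mean": float(obs_pop.mean()),
        "observed_sample_mean": obs_mean,
        "observed_sample_ci": (obs_mean - 1.96 * obs_se, obs_mean + 1.96 * obs_se),
        "predicted_sample_mean": float(pred_sample.mean()),
        "q_star": search.q_star,
        "top_q_mean": search.top_q_mean,
        "landmarks": search.landmarks,
        "curve": search.curve,
    }
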