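"""Synthetic data generation with known truth for every pipeline stage.

Generates daily temperature series (sinusoid + AR1 noise + anomaly
blocks), fish cohorts whose daily growth follows the mixed-effects
generating model (fixed effects on standardized size and temperature,
class offsets, fish-level random intercept and slope, AR1 residuals),
otolith radii constructed by exactly inverting the biological-intercept
back-calculation so the otolith stage round-trips, allometric masses,
diets, and size-selective survival operators.

All randomness flows from named substreams of a single integer seed.
"""

from __future__ import annotations

import datetime as _dt
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureScenario",
    "CohortScenario",
    "SurvivalRule",
    "DietProfile",
    "substream",
    "generate_temperature",
    "generate_cohort",
    "apply_survival",
    "generate_diets",
    "simulate_growth_design",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child RNG of a root seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR1 series with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    shocks = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + shocks[t - 1]
    return e


# ---------------------------------------------------------------------------
# temperature


@dataclass
class TemperatureScenario:
    start_date: _dt.date
    end_date: _dt.date
    mean_annual: float = 8.0
    seasonal_amplitude: float = 4.0
    phase_day: int = 220  # day-of-year of the seasonal maximum
    ar1_phi: float = 0.8
    noise_sd: float = 0.5
    anomalies: list[tuple[_dt.date, int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("end_date precedes start_date")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")
        for _, dur, inten in self.anomalies:
            if dur <= 0 or inten < 0:
                raise ValueError("anomaly blocks need duration > 0 and intensity >= 0")


def generate_temperature(scenario: TemperatureScenario) -> pd.DataFrame:
    """Daily temperature table (date, temp_c): seasonal sinusoid plus
    stationary AR1 noise plus anomaly blocks (overlaps add)."""
    dates = pd.date_range(scenario.start_date, scenario.end_date, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = scenario.mean_annual + scenario.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - scenario.phase_day) / 365.25
    )
    rng = substream(scenario.seed, "temperature")
    noise = _ar1_noise(rng, len(dates), scenario.ar1_phi, scenario.noise_sd)
    temp = seasonal + noise
    for start, dur, inten in scenario.anomalies:
        block = (dates >= pd.Timestamp(start)) & (
            dates < pd.Timestamp(start) + pd.Timedelta(days=dur)
        )
        temp = temp + inten * block.astype(float)
    return pd.DataFrame({"date": dates.strftime("%Y-%m-%d"), "temp_c": temp})


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortScenario:
    """Generating truth for fish cohorts.

    ``growth_coefficients`` act on the log relative-growth scale with
    standardized covariates: keys intercept, size, temperature,
    class_between, class_during.  ``scale_ref`` holds the (mean, sd)
    standardization constants for size (mm) and temperature (degC) used
    by the generating model.
    """

    n_fish: dict[tuple[int, int, str], int]
    settlement_length_mean: float = 45.0
    settlement_length_sd: float = 4.0
    growth_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -4.43,
            "size": -0.12,
            "temperature": -0.11,
            "class_between": 0.07,
            "class_during": 0.15,
        }
    )
    scale_ref: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"size": (60.0, 15.0), "temperature": (9.5, 1.5)}
    )
    fish_intercept_sd: float = 0.1
    day_slope_sd: float = 0.01
    resid_sd: float = 0.15
    resid_ar1_phi: float = 0.3
    allometry: tuple[float, float, float] = (-11.83, 3.07, 0.1)
    hsi_mean: float = 2.0
    hsi_sd: float = 0.5
    biological_intercept: tuple[float, float] = (3.9, 8.3)
    otolith_relation: tuple[float, float, float] = (0.0, 10.0, 0.0)  # O_c = a + b*L_c (+sd)
    window: int = 21
    capture_day: int = 15
    inter_sampling_days: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("settlement_length_sd", "fish_intercept_sd", "day_slope_sd",
                     "resid_sd", "hsi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        L0, O0 = self.biological_intercept
        if L0 <= 0 or O0 <= 0:
            raise ValueError("biological intercept must be positive")
        if any(n < 0 for n in self.n_fish.values()):
            raise ValueError("n_fish counts must be >= 0")


def _class_offset(coefs: dict[str, float], cls: str) -> float:
    key = {"Between": "class_between", "Heatwave": "class_during",
           "During": "class_during"}.get(cls)
    return coefs.get(key, 0.0) if key else 0.0


def generate_cohort(
    scenario: CohortScenario, temps: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fish with daily growth trajectories and consistent otoliths.

    Returns (fish table, otolith table).  Daily log relative growth is
    the fixed-effect predictor plus fish random intercept, day slope on
    the centered increment index, and a stationary AR1 residual; lengths
    compound multiplicatively; otolith radii invert the back-calculation
    exactly; mass follows the configured allometry with lognormal noise.
    """
    temp_lookup = pd.Series(
        temps["temp_c"].to_numpy(float),
        index=pd.DatetimeIndex(pd.to_datetime(temps["date"])),
    )
    coefs = scenario.growth_coefficients
    s_mu, s_sd = scenario.scale_ref["size"]
    t_mu, t_sd = scenario.scale_ref["temperature"]
    L0, O0 = scenario.biological_intercept
    o_a, o_b, o_sd = scenario.otolith_relation
    w = scenario.window
    center = (w + 1) / 2.0

    fish_rows, oto_rows = [], []
    counter = 0
    for (year, month, cls), n in sorted(scenario.n_fish.items()):
        if n == 0:
            continue
        capture = pd.Timestamp(year=year, month=month, day=scenario.capture_day)
        days = pd.date_range(capture - pd.Timedelta(days=w), capture, freq="D")
        try:
            day_temps = temp_lookup.loc[days[1:]].to_numpy(float)
        except KeyError as exc:
            raise ValueError(
                f"temperature series does not cover the {w} days before {capture.date()}"
            ) from exc
        rng = substream(scenario.seed, f"cohort/{year}/{month}/{cls}")
        for _ in range(n):
            counter += 1
            fid = f"F{counter:05d}"
            b0 = rng.normal(0.0, scenario.fish_intercept_sd)
            b1 = rng.normal(0.0, scenario.day_slope_sd)
            resid = _ar1_noise(rng, w, scenario.resid_ar1_phi, scenario.resid_sd)
            L = np.empty(w + 1)
            L[0] = rng.normal(scenario.settlement_length_mean,
                              scenario.settlement_length_sd)
            if L[0] <= 0:
                raise ValueError("implausible scenario: non-positive start length")
            for t in range(1, w + 1):
                eta = (
                    coefs.get("intercept", 0.0)
                    + coefs.get("size", 0.0) * (L[t - 1] - s_mu) / s_sd
                    + coefs.get("temperature", 0.0) * (day_temps[t - 1] - t_mu) / t_sd
                    + _class_offset(coefs, cls)
                    + b0 + b1 * (t - center) + resid[t - 1]
                )
                L[t] = L[t - 1] * (1.0 + np.exp(eta))
            Lc = L[-1]
            if Lc <= L0:
                raise ValueError("implausible scenario: capture length below intercept")
            Oc = o_a + o_b * Lc + (rng.normal(0.0, o_sd) if o_sd > 0 else 0.0)
            if Oc <= O0:
                raise ValueError("implausible scenario: otolith radius below intercept")
            radii = Oc + (L - Lc) * (Oc - O0) / (Lc - L0)
            ln_a, ln_b, ln_sd = scenario.allometry
            mass = float(np.exp(ln_a + ln_b * np.log(Lc)
                                + (rng.normal(0.0, ln_sd) if ln_sd > 0 else 0.0)))
            hsi = max(rng.normal(scenario.hsi_mean, scenario.hsi_sd), 0.0)
            fish_rows.append({
                "fish_id": fid, "year": year, "month": month, "class": cls,
                "site": f"S{1 + counter % 4}", "haul": 1 + counter % 3,
                "sl_mm": Lc, "mass_g": mass, "liver_g": hsi / 100.0 * mass,
            })
            for a in range(w + 1):
                oto_rows.append({
                    "fish_id": fid, "increment_index": a,
                    "radius_um": radii[a], "radius_at_capture_um": Oc,
                })
    return pd.DataFrame(fish_rows), pd.DataFrame(oto_rows)


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalRule:
    mode: str = "none"  # none | quantile_truncation | logistic_by_size
    q_survive: float = 1.0
    l50: float = 75.0
    slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"none", "quantile_truncation", "logistic_by_size"}:
            raise ValueError(f"unknown survival mode {self.mode!r}")
        if not 0 < self.q_survive <= 1:
            raise ValueError("q_survive must be in (0, 1]")


def apply_survival(fish: pd.DataFrame, rule: SurvivalRule) -> pd.DataFrame:
    """Apply a size-selective survival operator to a fish table."""
    if fish.empty:
        raise ValueError("fish table is empty")
    if rule.mode == "none":
        return fish.copy()
    if rule.mode == "quantile_truncation":
        k = int(np.ceil(rule.q_survive * len(fish)))
        return fish.nlargest(k, "sl_mm")
    rng = substream(rule.seed, "survival")
    from scipy.special import expit

    p = expit(rule.slope * (fish["sl_mm"].to_numpy(float) - rule.l50))
    return fish[rng.random(len(fish)) < p]


# ---------------------------------------------------------------------------
# diets


@dataclass
class DietProfile:
    """Per (class, month) prey mixtures.

    ``mixtures`` maps (class, month) to a taxon map of
    (probability, mean count per occurrence, mean item weight mg).
    """

    mixtures: dict[tuple[str, int], dict[str, tuple[float, float, float]]]
    empty_probability: float = 0.02
    weight_cv: float = 0.3
    mean_items: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.empty_probability <= 1:
            raise ValueError("empty_probability must be in [0, 1]")
        for key, taxa in self.mixtures.items():
            total = sum(p for p, _, _ in taxa.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"probabilities for {key} sum to {total}, not 1")


def generate_diets(fish: pd.DataFrame, profile: DietProfile) -> pd.DataFrame:
    """Stomach table: per fish an empty stomach with the configured
    probability, else a multinomial draw of prey items with lognormal
    per-item weights.  Empty stomachs appear as a row with blank taxon."""
    rng = substream(profile.seed, "diets")
    rows = []
    for r in fish.to_dict("records"):
        cls, month = r["class"], r["month"]
        if (cls, month) not in profile.mixtures:
            raise ValueError(f"no diet mixture for class {cls!r}, month {month}")
        mix = profile.mixtures[(cls, month)]
        if rng.random() < profile.empty_probability:
            rows.append({"fish_id": r["fish_id"], "prey_taxon": "", "count": 0,
                         "weight_mg": 0.0, "stomach_total_g": 0.0,
                         "fish_total_g": r["mass_g"]})
            continue
        taxa = list(mix)
        probs = np.array([mix[t][0] for t in taxa])
        n_items = 1 + rng.poisson(max(profile.mean_items - 1, 0.0))
        counts = rng.multinomial(n_items, probs)
        total_mg = 0.0
        stomach_rows = []
        for taxon, c in zip(taxa, counts):
            if c == 0:
                continue
            mean_w = mix[taxon][2]
            sigma = np.sqrt(np.log(1.0 + profile.weight_cv**2))
            mu = np.log(mean_w) - 0.5 * sigma**2
            wsum = float(rng.lognormal(mu, sigma, size=c).sum())
            total_mg += wsum
            stomach_rows.append({"fish_id": r["fish_id"], "prey_taxon": taxon,
                                 "count": int(c), "weight_mg": wsum})
        for sr in stomach_rows:
            sr["stomach_total_g"] = total_mg / 1000.0
            sr["fish_total_g"] = r["mass_g"] + total_mg / 1000.0
            rows.append(sr)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# direct growth-design simulation (for parameter-recovery experiments)


def simulate_growth_design(
    n_fish: int,
    coefs: dict[str, float],
    n_increments: int = 21,
    sd_intercept: float = 0.1,
    sd_slope: float = 0.01,
    sd_resid: float = 0.15,
    ar1_phi: float = 0.3,
    class_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a growth-observation table directly from the mixed model.

    Standardized covariates are drawn fresh: size constant within fish
    (N(0,1) across fish), temperature per observation (N(0,1)).  The
    response is the linear predictor plus fish random intercept, random
    slope on the centered increment, and stationary AR1 residuals.
    Returns columns fish_id, class, increment_index, size, temperature,
    log_growth.
    """
    class_probs = class_probs or {"Before": 0.4, "Between": 0.3, "Heatwave": 0.3}
    classes = list(class_probs)
    probs = np.array([class_probs[c] for c in classes], float)
    probs = probs / probs.sum()
    rng = substream(seed, "growth-design")
    center = (n_increments + 1) / 2.0
    inc = np.arange(1, n_increments + 1)
    rows = []
    for i in range(n_fish):
        fid = f"F{i + 1:05d}"
        cls = classes[rng.choice(len(classes), p=probs)]
        size = rng.normal()
        temp = rng.normal(size=n_increments)
        b0 = rng.normal(0.0, sd_intercept)
        b1 = rng.normal(0.0, sd_slope)
        e = _ar1_noise(rng, n_increments, ar1_phi, sd_resid)
        eta = (
            coefs.get("intercept", 0.0)
            + coefs.get("size", 0.0) * size
            + coefs.get("temperature", 0.0) * temp
            + _class_offset(coefs, cls)
            + b0 + b1 * (inc - center) + e
        )
        for t in range(n_increments):
            rows.append({
                "fish_id": fid, "class": cls, "increment_index": int(inc[t]),
                "size": size, "temperature": temp[t], "log_growth": eta[t],
            })
    return pd.DataFrame(rows)
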