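"""Marine heatwave detection from daily temperature series.

Implements the standard climatology / 90th-percentile definition: a
day-of-year climatology built from a multi-year baseline with a centered
pooling window and moving-average smoothing, event detection as runs of
at least ``min_duration`` days above threshold with short gaps joined,
ordinal severity categories from multiples of the threshold-climatology
gap, and binning of years into heatwave classes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Climatology",
    "MHWEvent",
    "YearClassification",
    "CATEGORY_NAMES",
    "build_climatology",
    "detect_events",
    "categorize",
    "classify_years",
    "heatwave_day_counts",
    "PAPER_YEAR_CLASSES",
]

CATEGORY_NAMES = {1: "Moderate", 2: "Strong", 3: "Severe", 4: "Extreme"}

#: Published year binning used for validation fixtures.
PAPER_YEAR_CLASSES = {
    **{y: "Before" for y in range(2006, 2014)},
    **{y: "Heatwave" for y in (2014, 2015, 2016, 2019)},
    **{y: "Between" for y in (2017, 2018)},
}


def _as_series(temps: pd.DataFrame | pd.Series) -> pd.Series:
    """Coerce input to a date-indexed temperature Series and validate."""
    if isinstance(temps, pd.DataFrame):
        if not {"date", "temp_c"}.issubset(temps.columns):
            raise ValueError("temperature table needs 'date' and 'temp_c' columns")
        s = pd.Series(
            temps["temp_c"].to_numpy(float),
            index=pd.DatetimeIndex(pd.to_datetime(temps["date"])),
        )
    else:
        s = pd.Series(temps.to_numpy(float), index=pd.DatetimeIndex(temps.index))
    if not s.index.is_monotonic_increasing:
        raise ValueError("temperature dates must be strictly increasing")
    if s.index.has_duplicates:
        raise ValueError("duplicate dates in temperature series")
    return s


def _leap_doy(index: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on a fixed 366-day (leap) calendar, so that a given
    (month, day) always maps to the same integer; Feb 29 -> 60."""
    doy = index.dayofyear.to_numpy().copy()
    not_leap = ~index.is_leap_year
    after_feb = doy >= 60
    doy[not_leap & after_feb] += 1
    return doy


@dataclass
class Climatology:
    """Day-of-year mean and 90th-percentile threshold.

    Arrays are indexed by leap-calendar day-of-year (1..366 at positions
    0..365; position 59 is Feb 29).
    """

    mean: np.ndarray
    threshold90: np.ndarray
    baseline: tuple[int, int]
    percentile: float = 90.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.threshold90 = np.asarray(self.threshold90, float)
        if self.mean.shape != (366,) or self.threshold90.shape != (366,):
            raise ValueError("climatology arrays must have length 366")

    def lookup(self, dates: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
        idx = _leap_doy(pd.DatetimeIndex(dates)) - 1
        return self.mean[idx], self.threshold90[idx]


@dataclass
class MHWEvent:
    start: _dt.date
    end: _dt.date
    duration: int
    max_intensity: float
    cumulative_intensity: float
    category: str = ""
    category_rank: int = 0
    peak_date: _dt.date | None = None

    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


@dataclass
class YearClassification:
    classes: dict[int, str]
    day_counts: dict[int, int] = field(default_factory=dict)


def _circular_smooth(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with circular wrap; width forced odd."""
    if width <= 1:
        return x.copy()
    if width % 2 == 0:
        width += 1
    h = width // 2
    padded = np.concatenate([x[-h:], x, x[:h]])
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def build_climatology(
    temps: pd.DataFrame | pd.Series,
    baseline: tuple[int, int],
    window_half_width: int = 5,
    smooth_width: int = 31,
    percentile: float = 90.0,
) -> Climatology:
    """Build a day-of-year climatology from a daily temperature series.

    For each day-of-year (Feb 29 excluded from pooling), all baseline
    temperatures within ``window_half_width`` days (circular across the
    year boundary) enter the pool; the pool mean and the requested
    percentile (linear interpolation between order statistics) are then
    smoothed with a circular centered moving average of ``smooth_width``
    days.  Feb 29 is the average of the Feb 28 and Mar 1 values.
    Missing days are simply absent from the pools.
    """
    s = _as_series(temps).dropna()
    y0, y1 = baseline
    if y1 < y0:
        raise ValueError("baseline end year precedes start year")
    sel = s[(s.index.year >= y0) & (s.index.year <= y1)]
    if sel.empty:
        raise ValueError("series does not cover the baseline period")
    n_years = sel.index.year.nunique()
    if n_years < 10:
        import warnings

        warnings.warn(
            f"climatology baseline has only {n_years} year(s); >=10 recommended",
            stacklevel=2,
        )

    doy = _leap_doy(sel.index)
    vals = sel.to_numpy()
    # Work on the 365-day cycle (skip Feb 29 pools) then interpolate it.
    keep = doy != 60
    doy365 = doy[keep].copy()
    doy365[doy365 > 60] -= 1  # 1..365
    v365 = vals[keep]

    order = np.argsort(doy365, kind="stable")
    doy365 = doy365[order]
    v365 = v365[order]
    # bucket values by day for fast circular-window pooling
    buckets: list[np.ndarray] = [np.empty(0)] * 366  # 1-based; [0] unused
    left = np.searchsorted(doy365, np.arange(1, 367))
    for d in range(1, 366):
        buckets[d] = v365[left[d - 1] : left[d]]

    mean365 = np.empty(365)
    thr365 = np.empty(365)
    w = window_half_width
    for d in range(1, 366):
        idxs = [(d - 1 + off) % 365 + 1 for off in range(-w, w + 1)]
        pool = np.concatenate([buckets[i] for i in idxs])
        if pool.size == 0:
            raise ValueError(f"empty climatology window at day-of-year {d}")
        mean365[d - 1] = pool.mean()
        thr365[d - 1] = np.percentile(pool, percentile)

    mean365 = _circular_smooth(mean365, smooth_width)
    thr365 = _circular_smooth(thr365, smooth_width)

    mean366 = np.empty(366)
    thr366 = np.empty(366)
    mean366[:59] = mean365[:59]
    thr366[:59] = thr365[:59]
    mean366[60:] = mean365[59:]
    thr366[60:] = thr365[59:]
    mean366[59] = 0.5 * (mean365[58] + mean365[59])  # Feb 29
    thr366[59] = 0.5 * (thr365[58] + thr365[59])
    return Climatology(mean366, thr366, baseline, percentile)


def detect_events(
    temps: pd.DataFrame | pd.Series,
    clim: Climatology,
    min_duration: int = 5,
    max_gap: int = 2,
) -> list[MHWEvent]:
    """Detect heatwave events: maximal runs of days above the day-of-year
    threshold lasting at least ``min_duration`` days; qualifying events
    separated by at most ``max_gap`` below-threshold days are merged.

    Gap days count toward duration but only above-climatology days
    contribute to cumulative intensity.  Events are categorized against
    the climatology before being returned.
    """
    s = _as_series(temps)
    # operate on contiguous runs only: reindex to full daily range
    full = s.reindex(pd.date_range(s.index[0], s.index[-1], freq="D"))
    dates = full.index
    vals = full.to_numpy()
    mean, thr = clim.lookup(dates)
    # tolerance absorbs smoothing round-off so a series equal to its own
    # climatology never registers as exceedance
    above = np.where(np.isnan(vals), False, vals > thr + 1e-9)

    runs: list[tuple[int, int]] = []
    i = 0
    n = len(vals)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_duration:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1

    merged: list[tuple[int, int]] = []
    for st, en in runs:
        if merged and st - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], en)
        else:
            merged.append((st, en))

    events: list[MHWEvent] = []
    for st, en in merged:
        anom = vals[st : en + 1] - mean[st : en + 1]
        anom = np.where(np.isnan(anom), -np.inf, anom)
        peak_off = int(np.argmax(anom))
        max_int = float(anom[peak_off])
        cum_int = float(anom[(anom > 0) & np.isfinite(anom)].sum())
        ev = MHWEvent(
            start=dates[st].date(),
            end=dates[en].date(),
            duration=en - st + 1,
            max_intensity=max_int,
            cumulative_intensity=cum_int,
            peak_date=dates[st + peak_off].date(),
        )
        try:
            ev.category_rank, ev.category = categorize(ev, clim)
        except ValueError:
            ev.category_rank, ev.category = 0, ""  # degenerate flat climatology
        events.append(ev)
    return events


def categorize(event: MHWEvent, clim: Climatology) -> tuple[int, str]:
    """Severity category from the peak anomaly as a multiple of the local
    threshold-climatology gap: 1 Moderate, 2 Strong, 3 Severe, >=4 Extreme."""
    peak = pd.DatetimeIndex([pd.Timestamp(event.peak_date or event.start)])
    mean, thr = clim.lookup(peak)
    gap = float(thr[0] - mean[0])
    if gap <= 0:
        raise ValueError(
            f"degenerate climatology at {event.peak_date}: threshold equals mean"
        )
    k = int(event.max_intensity // gap)
    k = max(1, min(k, 4))
    return k, CATEGORY_NAMES[k]


def heatwave_day_counts(
    events: list[MHWEvent], years: list[int] | None = None
) -> dict[int, int]:
    """Number of event days falling in each calendar year."""
    counts: dict[int, int] = {y: 0 for y in years} if years else {}
    for ev in events:
        for d in ev.days():
            if years is None:
                counts[d.year] = counts.get(d.year, 0) + 1
            elif d.year in counts:
                counts[d.year] += 1
    return counts


def classify_years(
    events: list[MHWEvent],
    years: list[int],
    min_heatwave_days: int = 30,
) -> YearClassification:
    """Bin years into Before / Heatwave / Between classes.

    A year with at least ``min_heatwave_days`` event days is a Heatwave
    year; non-heatwave years after the first Heatwave year are Between;
    earlier years are Before.
    """
    counts = heatwave_day_counts(events, years)
    hw_years = sorted(y for y, c in counts.items() if c >= min_heatwave_days)
    classes: dict[int, str] = {}
    first_hw = hw_years[0] if hw_years else None
    for y in sorted(years):
        if counts[y] >= min_heatwave_days:
            classes[y] = "Heatwave"
        elif first_hw is not None and y > first_hw:
            classes[y] = "Between"
        else:
            classes[y] = "Before"
    return YearClassification(classes=classes, day_counts=counts)


def events_to_frame(events: list[MHWEvent]) -> pd.DataFrame:
    """Tabulate events with the standard output columns."""
    return pd.DataFrame(
        {
            "start": [e.start.isoformat() for e in events],
            "end": [e.end.isoformat() for e in events],
            "duration_days": [e.duration for e in events],
            "max_intensity_c": [e.max_intensity for e in events],
            "cum_intensity_c_days": [e.cumulative_intensity for e in events],
            "category": [e.category for e in events],
        }
    )
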