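import datetime as dt

import numpy as np
import pandas as pd
import pytest

from mhwnursery import mhw
from mhwnursery import synthetic as syn


def _series(values, start="2000-01-01"):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame({"date": dates.strftime("%Y-%m-%d"), "temp_c": values})


class TestClimatology:
    def test_constant_series_degenerate(self, flat_temp_series):
        clim = mhw.build_climatology(flat_temp_series, (2000, 2011))
        assert np.allclose(clim.mean, 10.0)
        assert np.allclose(clim.threshold90, 10.0)

    def test_sinusoid_reproduced_within_smoothing_bias(self, sinusoid_scenario):
        temps = syn.generate_temperature(sinusoid_scenario)
        clim = mhw.build_climatology(temps, (2000, 2013))
        dates = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        truth = 8.0 + 3.0 * np.cos(2 * np.pi * (doy - 220) / 365.25)
        got, _ = clim.lookup(dates)
        assert np.max(np.abs(got - truth)) < 0.05

    def test_day1_pool_is_circular(self):
        # December much warmer than January: day-1 climatology must feel it
        dates = pd.date_range("2000-01-01", "2010-12-31", freq="D")
        temp = np.where(dates.month == 12, 20.0, 5.0)
        clim = mhw.build_climatology(_series(temp), (2000, 2010))
        jan1 = clim.mean[0]
        jul1 = clim.mean[181]
        assert jan1 > jul1 + 1.0  # pulled up by late-December pool days

    def test_year_permutation_invariance(self, rng):
        dates = pd.date_range("2000-01-01", "2009-12-31", freq="D")
        base = rng.normal(8.0, 1.5, size=len(dates))
        df = _series(base)
        clim1 = mhw.build_climatology(df, (2000, 2009))
        # permute whole years: swap the values of 2002 and 2007 (same doy grid)
        d = pd.to_datetime(df["date"])
        y2 = (d.dt.year == 2002) & ~((d.dt.month == 2) & (d.dt.day == 29))
        y7 = (d.dt.year == 2007) & ~((d.dt.month == 2) & (d.dt.day == 29))
        v = df["temp_c"].to_numpy().copy()
        v[np.flatnonzero(y2)], v[np.flatnonzero(y7)] = (
            v[np.flatnonzero(y7)].copy(), v[np.flatnonzero(y2)].copy(),
        )
        clim2 = mhw.build_climatology(_series(v), (2000, 2009))
        assert np.allclose(clim1.mean, clim2.mean)
        assert np.allclose(clim1.threshold90, clim2.threshold90)

    def test_baseline_outside_series_rejected(self, flat_temp_series):
        with pytest.raises(ValueError):
            mhw.build_climatology(flat_temp_series, (2050, 2060))

    def test_short_baseline_warns(self, flat_temp_series):
        with pytest.warns(UserWarning, match="baseline"):
            mhw.build_climatology(flat_temp_series, (2000, 2003))


class TestDetectEvents:
    def test_constant_at_climatology_no_events(self, flat_temp_series):
        clim = mhw.build_climatology(flat_temp_series, (2000, 2011))
        assert mhw.detect_events(flat_temp_series, clim) == []

    def test_single_block_duration_and_intensity(self, flat_temp_series):
        clim = mhw.build_climatology(flat_temp_series, (2000, 2011))
        temp = np.full(365, 10.0)
        temp[100:110] += 5.0
        events = mhw.detect_events(_series(temp, "2012-01-01"), clim)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration == 10
        assert ev.max_intensity == pytest.approx(5.0)
        assert ev.cumulative_intensity == pytest.approx(50.0)

    def test_gap_joining(self, flat_temp_series):
        clim = mhw.build_climatology(flat_temp_series, (2000, 2011))
        temp = np.full(365, 10.0)
        temp[100:105] += 3.0  # 5-day run
        temp[107:112] += 3.0  # 2-day dip then 5-day run
        events = mhw.detect_events(_series(temp, "2012-01-01"), clim)
        assert len(events) == 1
        assert events[0].duration == 12
        # gap days below climatology excluded from the intensity sum
        assert events[0].cumulative_intensity == pytest.approx(30.0)

    def test_gap_longer_than_max_not_joined(self, flat_temp_series):
        clim = mhw.build_climatology(flat_temp_series, (2000, 2011))
        temp = np.full(365, 10.0)
        temp[100:105] += 3.0
        temp[108:113] += 3.0  # 3-day gap
        events = mhw.detect_events(_series(temp, "2012-01-01"), clim)
        assert [e.duration for e in events] == [5, 5]

    def test_runs_shorter_than_min_duration_ignored(self, flat_temp_series):
        clim = mhw.build_climatology(flat_temp_series, (2000, 2011))
        temp = np.full(100, 10.0)
        temp[10:14] += 4.0  # 4 days < 5
        assert mhw.detect_events(_series(temp, "2012-01-01"), clim) == []

    def test_translation_invariance(self, rng):
        dates = pd.date_range("2000-01-01", "2012-12-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        temp = 8 + 3 * np.cos(2 * np.pi * (doy - 220) / 365.25) + rng.normal(0, 1, len(dates))
        df1 = _series(temp)
        df2 = _series(temp + 4.0)
        c1 = mhw.build_climatology(df1, (2000, 2011))
        c2 = mhw.build_climatology(df2, (2000, 2011))
        e1 = mhw.detect_events(df1, c1)
        e2 = mhw.detect_events(df2, c2)
        assert [(e.start, e.end) for e in e1] == [(e.start, e.end) for e in e2]
        for a, b in zip(e1, e2):
            assert a.cumulative_intensity == pytest.approx(b.cumulative_intensity)

    def test_event_invariants(self, rng):
        dates = pd.date_range("2000-01-01", "2012-12-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        temp = 8 + 3 * np.cos(2 * np.pi * (doy - 220) / 365.25) + rng.normal(0, 1.2, len(dates))
        df = _series(temp)
        clim = mhw.build_climatology(df, (2000, 2011))
        for ev in mhw.detect_events(df, clim):
            assert ev.duration >= 5
            assert ev.cumulative_intensity >= ev.max_intensity >= 0


class TestCategorize:
    @pytest.fixture()
    def clim_with_gap(self, flat_temp_series):
        # flat mean 10, threshold 11 (gap 1) built by hand
        return mhw.Climatology(np.full(366, 10.0), np.full(366, 11.0), (2000, 2011))

    @pytest.mark.parametrize(
        "peak_anomaly,expected",
        [(1.5, "Moderate"), (2.5, "Strong"), (3.2, "Severe"), (4.2, "Extreme"),
         (9.0, "Extreme")],
    )
    def test_category_multiples(self, clim_with_gap, peak_anomaly, expected):
        ev = mhw.MHWEvent(
            start=dt.date(2012, 6, 1), end=dt.date(2012, 6, 10), duration=10,
            max_intensity=peak_anomaly, cumulative_intensity=peak_anomaly * 10,
            peak_date=dt.date(2012, 6, 5),
        )
        rank, name = mhw.categorize(ev, clim_with_gap)
        assert name == expected

    def test_degenerate_gap_rejected(self):
        clim = mhw.Climatology(np.full(366, 10.0), np.full(366, 10.0), (2000, 2011))
        ev = mhw.MHWEvent(dt.date(2012, 6, 1), dt.date(2012, 6, 10), 10, 2.0, 20.0,
                          peak_date=dt.date(2012, 6, 5))
        with pytest.raises(ValueError, match="degenerate"):
            mhw.categorize(ev, clim)


class TestClassifyYears:
    def test_no_events_all_before(self):
        yc = mhw.classify_years([], list(range(2000, 2005)))
        assert set(yc.classes.values()) == {"Before"}

    def test_synthetic_heatwave_then_between(self):
        sc = syn.TemperatureScenario(
            start_date=dt.date(2000, 1, 1), end_date=dt.date(2012, 12, 31),
            seasonal_amplitude=3.0, ar1_phi=0.0, noise_sd=0.0,
            anomalies=[(dt.date(y, 6, 1), 90, 4.0) for y in (2009, 2010, 2011)],
            seed=0,
        )
        temps = syn.generate_temperature(sc)
        clim = mhw.build_climatology(temps, (2000, 2008))
        events = mhw.detect_events(temps, clim)
        yc = mhw.classify_years(events, list(range(2000, 2013)), min_heatwave_days=30)
        assert yc.classes[2009] == yc.classes[2010] == yc.classes[2011] == "Heatwave"
        assert yc.classes[2012] == "Between"
        assert yc.classes[2005] == "Before"

    def test_paper_fixture_mapping(self):
        classes = mhw.PAPER_YEAR_CLASSES
        assert all(classes[y] == "Before" for y in range(2006, 2014))
        assert all(classes[y] == "Heatwave" for y in (2014, 2015, 2016, 2019))
        assert all(classes[y] == "Between" for y in (2017, 2018))
        assert len(classes) == 14
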