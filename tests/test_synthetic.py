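import datetime as dt

import numpy as np
import pandas as pd
import pytest

from mhwnursery import otolith as oto
from mhwnursery import synthetic as syn


class TestTemperature:
    def _scenario(self, **kw):
        base = dict(start_date=dt.date(2000, 1, 1), end_date=dt.date(2001, 12, 31),
                    mean_annual=8.0, seasonal_amplitude=0.0, ar1_phi=0.0,
                    noise_sd=0.0, seed=0)
        base.update(kw)
        return syn.TemperatureScenario(**base)

    def test_flat_degenerate(self):
        temps = syn.generate_temperature(self._scenario())
        assert np.allclose(temps["temp_c"], 8.0)
        assert len(temps) == 731

    def test_anomaly_block_exact(self):
        sc = self._scenario(anomalies=[(dt.date(2000, 6, 1), 10, 5.0)])
        temps = syn.generate_temperature(sc)
        elevated = temps[temps["temp_c"] > 8.0]
        assert len(elevated) == 10
        assert np.allclose(elevated["temp_c"], 13.0)
        assert elevated["date"].iloc[0] == "2000-06-01"

    def test_overlapping_anomalies_add(self):
        sc = self._scenario(anomalies=[(dt.date(2000, 6, 1), 10, 5.0),
                                       (dt.date(2000, 6, 5), 10, 2.0)])
        temps = syn.generate_temperature(sc).set_index("date")
        assert temps.loc["2000-06-06", "temp_c"] == pytest.approx(15.0)

    def test_seed_determinism(self):
        sc = self._scenario(noise_sd=0.7, ar1_phi=0.6, seed=42)
        t1 = syn.generate_temperature(sc)
        t2 = syn.generate_temperature(sc)
        pd.testing.assert_frame_equal(t1, t2)

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            self._scenario(end_date=dt.date(1999, 1, 1))

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            self._scenario(ar1_phi=1.0)


class TestCohort:
    def _flat_temps(self):
        return syn.generate_temperature(syn.TemperatureScenario(
            start_date=dt.date(2013, 1, 1), end_date=dt.date(2014, 12, 31),
            mean_annual=9.5, seasonal_amplitude=0.0, ar1_phi=0.0, noise_sd=0.0,
            seed=0))

    def _deterministic_scenario(self, c=-4.0, size_coef=0.0, temp_coef=0.0):
        return syn.CohortScenario(
            n_fish={(2014, 7, "Before"): 4},
            settlement_length_sd=0.0,
            growth_coefficients={"intercept": c, "size": size_coef,
                                 "temperature": temp_coef},
            fish_intercept_sd=0.0, day_slope_sd=0.0, resid_sd=0.0,
            allometry=(-11.83, 3.07, 0.0), hsi_sd=0.0, seed=0,
        )

    def test_degenerate_constant_rate(self):
        fish, otos = syn.generate_cohort(self._deterministic_scenario(), self._flat_temps())
        tracks = oto.tracks_from_table(otos, fish)
        g = oto.relative_growth(oto.back_calculate_lengths(tracks[0]))
        assert np.allclose(g, np.exp(-4.0), rtol=1e-9)

    def test_roundtrip_zero_noise(self):
        fish, otos = syn.generate_cohort(self._deterministic_scenario(), self._flat_temps())
        # reconstruct the generated daily lengths independently
        L = np.empty(22)
        L[0] = 45.0
        for t in range(1, 22):
            L[t] = L[t - 1] * (1 + np.exp(-4.0))
        track = oto.tracks_from_table(otos, fish)[0]
        back = oto.back_calculate_lengths(track)
        assert np.max(np.abs(back - L)) < 1e-9

    def test_allometry_noise_zero_exact_line(self):
        fish, _ = syn.generate_cohort(self._deterministic_scenario(), self._flat_temps())
        lhs = np.log(fish["mass_g"])
        rhs = -11.83 + 3.07 * np.log(fish["sl_mm"])
        assert np.allclose(lhs, rhs)

    def test_seed_determinism(self, small_cohort):
        fish2, otos2 = syn.generate_cohort(small_cohort["scenario"],
                                           small_cohort["temps"])
        pd.testing.assert_frame_equal(small_cohort["fish"], fish2)
        pd.testing.assert_frame_equal(small_cohort["otoliths"], otos2)

    def test_temperature_coverage_required(self):
        sc = self._deterministic_scenario()
        short = syn.generate_temperature(syn.TemperatureScenario(
            start_date=dt.date(2014, 7, 10), end_date=dt.date(2014, 7, 20), seed=0))
        with pytest.raises(ValueError, match="cover"):
            syn.generate_cohort(sc, short)

    def test_allometry_residual_moments(self):
        sc = syn.CohortScenario(
            n_fish={(2014, 7, "Before"): 400},
            allometry=(-11.83, 3.07, 0.12), seed=9,
        )
        fish, _ = syn.generate_cohort(sc, self._flat_temps())
        resid = np.log(fish["mass_g"]) - (-11.83 + 3.07 * np.log(fish["sl_mm"]))
        assert abs(resid.mean()) < 0.02
        assert np.std(resid) == pytest.approx(0.12, abs=0.02)


class TestSurvival:
    def _fish(self, lengths):
        return pd.DataFrame({"fish_id": [f"f{i}" for i in range(len(lengths))],
                             "sl_mm": lengths})

    def test_mode_none_identity(self):
        fish = self._fish([60, 70, 80])
        out = syn.apply_survival(fish, syn.SurvivalRule(mode="none"))
        pd.testing.assert_frame_equal(out, fish)

    def test_quantile_truncation(self):
        fish = self._fish([60, 70, 80, 90])
        out = syn.apply_survival(
            fish, syn.SurvivalRule(mode="quantile_truncation", q_survive=0.5))
        assert sorted(out["sl_mm"]) == [80, 90]

    def test_logistic_steep_limit(self):
        fish = self._fish([60, 90])
        out = syn.apply_survival(
            fish, syn.SurvivalRule(mode="logistic_by_size", l50=75.0, slope=1e6,
                                   seed=0))
        assert list(out["sl_mm"]) == [90]

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            syn.SurvivalRule(mode="quantile_truncation", q_survive=0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            syn.apply_survival(self._fish([]), syn.SurvivalRule(mode="none"))


class TestDiets:
    def _fish(self, n=50, cls="Heatwave", month=7):
        return pd.DataFrame({
            "fish_id": [f"f{i}" for i in range(n)],
            "class": cls, "month": month, "mass_g": 2.0,
        })

    def _profile(self, empty_p=0.0, taxa=None, seed=0):
        taxa = taxa or {"mysid": (0.7, 3.0, 5.0), "copepod": (0.3, 8.0, 0.4)}
        return syn.DietProfile(
            mixtures={("Heatwave", 7): taxa}, empty_probability=empty_p, seed=seed)

    def test_all_empty(self):
        out = syn.generate_diets(self._fish(10), self._profile(empty_p=1.0))
        assert (out["prey_taxon"] == "").all()
        assert len(out) == 10

    def test_single_taxon(self):
        out = syn.generate_diets(
            self._fish(20), self._profile(taxa={"mysid": (1.0, 4.0, 5.0)}))
        assert set(out["prey_taxon"]) == {"mysid"}

    def test_empty_fraction_lln(self):
        n = 2000
        out = syn.generate_diets(self._fish(n), self._profile(empty_p=0.25, seed=3))
        frac = (out.groupby("fish_id")["prey_taxon"].first() == "").mean()
        # 3-sigma binomial band around 0.25
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_missing_profile_rejected(self):
        with pytest.raises(ValueError, match="mixture"):
            syn.generate_diets(self._fish(cls="Before"), self._profile())

    def test_weights_consistent(self):
        out = syn.generate_diets(self._fish(30), self._profile(seed=5))
        for _, grp in out.groupby("fish_id"):
            assert grp["stomach_total_g"].iloc[0] * 1000 == pytest.approx(
                grp["weight_mg"].sum())

    def test_probability_sum_validated(self):
        with pytest.raises(ValueError, match="sum"):
            syn.DietProfile(mixtures={("a", 7): {"x": (0.5, 1, 1), "y": (0.4, 1, 1)}})


class TestGrowthDesign:
    def test_zero_variance_exact_linear_predictor(self):
        coefs = {"intercept": -4.0, "size": -0.1, "temperature": 0.0,
                 "class_between": 0.0, "class_during": 0.0}
        df = syn.simulate_growth_design(10, coefs, sd_intercept=0.0, sd_slope=0.0,
                                       sd_resid=0.0, ar1_phi=0.0, seed=1)
        expected = -4.0 - 0.1 * df["size"]
        assert np.allclose(df["log_growth"], expected)

    def test_determinism(self):
        coefs = {"intercept": -4.4, "size": -0.12}
        d1 = syn.simulate_growth_design(20, coefs, seed=8)
        d2 = syn.simulate_growth_design(20, coefs, seed=8)
        pd.testing.assert_frame_equal(d1, d2)

    def test_shape(self):
        df = syn.simulate_growth_design(7, {"intercept": -4.0}, n_increments=21, seed=0)
        assert len(df) == 7 * 21
        assert df["increment_index"].max() == 21
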