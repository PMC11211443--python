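import datetime as dt

import numpy as np
import pandas as pd
import pytest

from mhwnursery import synthetic as syn


@pytest.fixture(scope="session")
def flat_temp_series():
    """Constant 10 degC daily series over 12 years."""
    dates = pd.date_range("2000-01-01", "2011-12-31", freq="D")
    return pd.DataFrame({"date": dates.strftime("%Y-%m-%d"), "temp_c": 10.0})


@pytest.fixture(scope="session")
def sinusoid_scenario():
    return syn.TemperatureScenario(
        start_date=dt.date(2000, 1, 1),
        end_date=dt.date(2014, 12, 31),
        mean_annual=8.0,
        seasonal_amplitude=3.0,
        phase_day=220,
        ar1_phi=0.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic-ish small cohort with temperatures covering captures."""
    temps = syn.generate_temperature(
        syn.TemperatureScenario(
            start_date=dt.date(2013, 1, 1), end_date=dt.date(2015, 12, 31),
            noise_sd=0.2, seed=11,
        )
    )
    scenario = syn.CohortScenario(
        n_fish={
            (2014, 7, "Heatwave"): 8,
            (2014, 8, "Heatwave"): 8,
            (2015, 7, "Before"): 8,
            (2015, 8, "Before"): 8,
        },
        seed=5,
    )
    fish, otoliths = syn.generate_cohort(scenario, temps)
    return {"temps": temps, "scenario": scenario, "fish": fish, "otoliths": otoliths}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
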