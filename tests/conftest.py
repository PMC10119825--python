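import pandas as pd
import pytest

from ucflow import ScenarioConfig, generate_demand, generate_proxies, generate_scenario


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free, drift-free weekly-cycle scenario (closed-form checkable)."""
    return ScenarioConfig(
        start_date="2015-01-01",
        end_date="2018-12-31",
        baseline_level=100.0,
        trend_annual_pct=0.0,
        yearly_amplitude=0.0,
        holiday_uplift=1.0,
        year_end_uplift=1.0,
        holiday_rule="none",
        noise_dispersion=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def quiet_scenario(quiet_config):
    series = generate_demand(quiet_config)
    panel = generate_proxies(quiet_config, series)
    return series, panel


@pytest.fixture(scope="session")
def drift_config():
    """Stochastic scenario with a level-4 lockdown episode."""
    return ScenarioConfig(
        start_date="2014-01-01",
        end_date="2020-12-31",
        baseline_level=150.0,
        alert_schedule=[("2020-03-26", "2020-05-13", 4), ("2020-08-12", "2020-09-21", 3)],
        seed=7,
    )


@pytest.fixture(scope="session")
def drift_scenario(drift_config):
    return generate_scenario(drift_config)


@pytest.fixture(scope="session")
def small_scenario():
    """Short stochastic scenario reaching just past a first test month."""
    cfg = ScenarioConfig(
        start_date="2014-01-01", end_date="2017-02-28", baseline_level=120.0, seed=3
    )
    return generate_scenario(cfg)
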