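"""Scaled-down concept-drift study: does the proxy-augmented model adapt?

A two-regime scenario (a level-4 lockdown halving demand in the drift year,
followed by a level-3 episode) is backtested weekly through a stable year and
the drift year with the reduced bank under all three feature-set ablations.
The quantities of interest are the Voting model's year-over-year MAPE
deterioration under each ablation — proxy-aware features should deteriorate
less than autoregressive-only ones — and the drift-year MAPE of the
proxy-only Voting model against the in-house benchmark.
"""

from __future__ import annotations

from .backtest import make_windows, run_backtest
from .bank import reduced_bank
from .metrics import drift_deterioration, yearly_breakdown
from .simulate import ScenarioConfig, generate_scenario

__all__ = ["drift_scenario_config", "run_drift_study", "STABLE_YEAR", "DRIFT_YEAR"]

STABLE_YEAR = 2019
DRIFT_YEAR = 2020


def drift_scenario_config(seed: int = 0) -> ScenarioConfig:
    """The study scenario: 2014-2020 demand, level-4 lockdown halving demand."""
    return ScenarioConfig(
        start_date="2014-01-01",
        end_date="2020-12-31",
        baseline_level=180.0,
        alert_schedule=[
            ("2020-03-26", "2020-05-13", 4),
            ("2020-08-12", "2020-09-21", 3),
        ],
        alert_effect={1: 1.0, 2: 0.85, 3: 0.65, 4: 0.5},
        seed=seed,
    )


def run_drift_study(seed: int = 0) -> dict[str, float]:
    """One seed of the drift study; returns the headline statistics.

    Keys: ``deterioration_<feature_set>`` (Voting year-over-year MAPE change,
    %), ``voting_mape_<year>_<feature_set>``, ``benchmark_mape_<year>`` and
    ``proxy_voting_mape_drift``.
    """
    series, panel = generate_scenario(drift_scenario_config(seed))
    windows = make_windows(series.start, f"{STABLE_YEAR}-01-01", series.end)
    results = run_backtest(
        series, panel, bank=reduced_bank(seed=seed), windows=windows, seed=seed
    )
    yearly = yearly_breakdown(results.records)

    out: dict[str, float] = {}
    for fs in ("all", "autoregressive_only", "proxy_only"):
        sub = yearly[yearly["feature_set"] == fs]
        out[f"deterioration_{fs}"] = drift_deterioration(
            sub, "Voting", STABLE_YEAR, DRIFT_YEAR
        )
        for year in (STABLE_YEAR, DRIFT_YEAR):
            row = sub[(sub["model"] == "Voting") & (sub["period"] == year)]
            out[f"voting_mape_{year}_{fs}"] = float(row["MAPE"].iloc[0])
    bench = yearly[(yearly["feature_set"] == "all") & (yearly["model"] == "Benchmark")]
    for year in (STABLE_YEAR, DRIFT_YEAR):
        out[f"benchmark_mape_{year}"] = float(
            bench[bench["period"] == year]["MAPE"].iloc[0]
        )
    out["proxy_voting_mape_drift"] = out[f"voting_mape_{DRIFT_YEAR}_proxy_only"]
    return out
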