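"""Error metrics, Theil's U, Diebold-Mariano, mean ranks, drift statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ucflow import (
    AlignedForecasts,
    ConfigurationError,
    DegenerateInputError,
    ablation_improvement,
    dm_test,
    drift_deterioration,
    mae,
    mape,
    mean_ranks,
    metric_table,
    rmse,
    theils_u,
    yearly_breakdown,
)
from ucflow.metrics import round_half_away


class TestPointMetrics:
    def test_perfect_forecast_zeroes_all_metrics(self):
        y = np.array([50.0, 60.0, 70.0])
        assert mape(y, y) == 0.0
        assert rmse(y, y) == 0.0
        assert mae(y, y) == 0.0

    def test_mape_worked_examples(self):
        assert mape([100.0, 100.0], [110.0, 90.0]) == pytest.approx(10.0)
        assert mape([50.0], [60.0]) == pytest.approx(20.0)

    def test_mape_excludes_zero_observations_by_default(self):
        assert mape([0.0, 100.0], [5.0, 110.0]) == pytest.approx(10.0)
        with pytest.raises(DegenerateInputError):
            mape([0.0, 100.0], [5.0, 110.0], zero_policy="raise")

    def test_rmse_worked_examples(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert rmse([10.0], [7.0]) == pytest.approx(3.0)

    def test_mae_worked_examples(self):
        assert mae([0.0, 0.0], [3.0, -4.0]) == pytest.approx(3.5)
        assert mae([5.0, 5.0], [7.0, 7.0]) == pytest.approx(2.0)

    def test_rmse_dominates_mae_with_equality_iff_equal_magnitudes(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.uniform(10, 100, size=20)
            f = y + rng.normal(0, 5, size=20)
            assert rmse(y, f) >= mae(y, f) - 1e-12
        y = np.zeros(5)
        f = np.array([2.0, -2.0, 2.0, -2.0, 2.0])
        assert rmse(y, f) == pytest.approx(mae(y, f))

    def test_scale_free_metrics_are_permutation_invariant(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(10, 100, 30)
        f = y + rng.normal(0, 4, 30)
        perm = rng.permutation(30)
        assert mape(y, f) == pytest.approx(mape(y[perm], f[perm]))
        assert rmse(y, f) == pytest.approx(rmse(y[perm], f[perm]))


class TestTheilsU:
    def test_one_step_persistence_scores_exactly_one(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(50, 150, 40)
        yhat = np.empty_like(y)
        yhat[1:] = y[:-1]  # forecast = previous observation
        yhat[0] = y[0]
        assert theils_u(y, yhat) == pytest.approx(1.0)

    def test_perfect_forecast_scores_zero(self):
        y = np.array([10.0, 20.0, 15.0, 25.0])
        assert theils_u(y, y) == 0.0

    def test_hand_computed_example(self):
        u = theils_u([10.0, 20.0, 10.0], [0.0, 15.0, 15.0])
        assert u == pytest.approx(0.5)

    def test_constant_series_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            u = theils_u([5.0, 5.0, 5.0], [6.0, 6.0, 6.0])
        assert np.isnan(u)

    def test_order_dependence(self):
        y = np.array([10.0, 20.0, 12.0, 30.0, 11.0])
        f = y + np.array([1.0, -2.0, 3.0, -1.0, 2.0])
        u1 = theils_u(y, f)
        u2 = theils_u(y[::-1], f[::-1])
        assert u1 != pytest.approx(u2)


class TestDieboldMariano:
    def test_identical_forecasts_are_degenerate(self):
        y = np.arange(20.0) + 50
        f = y + 1.0
        with pytest.raises(DegenerateInputError):
            dm_test(AlignedForecasts(y, f), AlignedForecasts(y, f))

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(80, 120, 100)
        a = AlignedForecasts(y, y + rng.normal(0, 5, 100))
        b = AlignedForecasts(y, y + rng.normal(0, 9, 100))
        s_ab, p_ab = dm_test(a, b)
        s_ba, p_ba = dm_test(b, a)
        assert s_ab == pytest.approx(-s_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_size_under_the_null(self):
        """Equal-variance forecast noise: rejection rate ~ nominal 5%.

        Replicates are chosen so the Monte-Carlo standard error (~0.004) is
        small against the width of the calibration band.
        """
        rng = np.random.default_rng(12345)
        T, reps = 286, 4000
        rejections = 0
        for _ in range(reps):
            y = rng.uniform(100, 200, T)
            a = AlignedForecasts(y, y + rng.normal(0, 10, T))
            b = AlignedForecasts(y, y + rng.normal(0, 10, T))
            _, p = dm_test(a, b, horizon=7)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_when_noise_doubles(self):
        """Doubled forecast-noise sd is detected at the 1% level."""
        rng = np.random.default_rng(999)
        T, reps = 286, 200
        rejections = 0
        for _ in range(reps):
            y = rng.uniform(100, 200, T)
            a = AlignedForecasts(y, y + rng.normal(0, 20, T))
            b = AlignedForecasts(y, y + rng.normal(0, 10, T))
            _, p = dm_test(a, b, horizon=7)
            rejections += p < 0.01
        assert rejections / reps > 0.9


def _records(mape_by):
    """Build a synthetic report: model -> per-window absolute errors on y=100."""
    rows = []
    date0 = pd.Timestamp("2019-01-01")
    for (model, w), m in mape_by.items():
        year = (date0 + pd.Timedelta(days=7 * w)).year  # window labelled by test start
        for d in range(7):
            date = date0 + pd.Timedelta(days=7 * w + d)
            rows.append(("all", w, year, model, date, 100.0, 100.0 + m))
    return pd.DataFrame(
        rows, columns=["feature_set", "window_id", "year", "model", "date", "y", "yhat"]
    )


class TestRanks:
    def test_strict_dominance(self):
        rec = _records({("A", 0): 1, ("B", 0): 2, ("A", 1): 1, ("B", 1): 3})
        out = mean_ranks(rec).set_index("model")
        assert out.loc["A", "mean_rank"] == 1.0
        assert out.loc["B", "mean_rank"] == 2.0

    def test_ties_get_average_rank(self):
        rec = _records({("A", 0): 2, ("B", 0): 2, ("C", 0): 2})
        out = mean_ranks(rec)
        assert (out["mean_rank"] == 2.0).all()

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        models, windows = ["A", "B", "C"], [0, 1, 2]
        table = {(m, w): rng.uniform(1, 30) for m, w in itertools.product(models, windows)}
        rec = _records(table)
        out = mean_ranks(rec).set_index("model")["mean_rank"]
        for m in models:
            ranks = []
            for w in windows:
                vals = sorted(table[(mm, w)] for mm in models)
                ranks.append(vals.index(table[(m, w)]) + 1)
            assert out[m] == pytest.approx(np.mean(ranks))

    def test_rank_sum_identity_per_window(self):
        rng = np.random.default_rng(5)
        n = 5
        rec = _records({(f"M{i}", w): rng.uniform(1, 20) for i in range(n) for w in range(3)})
        from ucflow.metrics import _window_ranks

        ranked = _window_ranks(rec)
        sums = ranked.groupby("window_id")["rank"].sum()
        assert (sums == n * (n + 1) / 2).all()


class TestYearly:
    def test_single_year_matches_overall(self):
        rec = _records({("A", w): 3 + w for w in range(4)})
        overall = metric_table(rec)
        yearly = yearly_breakdown(rec)
        assert len(yearly) == 1
        assert yearly["MAPE"].iloc[0] == pytest.approx(overall["MAPE"].iloc[0])

    def test_pair_count_weighted_recombination(self):
        rng = np.random.default_rng(6)
        rec = _records({("A", w): rng.uniform(1, 10) for w in range(60)})
        # windows starting late Dec 2019 spill into 2020 -> two year labels
        yearly = yearly_breakdown(rec).set_index("period")
        counts = rec.groupby(rec["year"])["y"].count()
        combined = (yearly["MAPE"] * counts).sum() / counts.sum()
        assert combined == pytest.approx(metric_table(rec)["MAPE"].iloc[0])

    def test_window_straddling_new_year_counts_to_start_year(self):
        rec = _records({("A", 52): 5.0})  # test_start 2019-12-30, spills to Jan 2020
        yearly = yearly_breakdown(rec)
        assert list(yearly["period"]) == [2019]


class TestDriftStatistics:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["model", "feature_set", "period", "MAPE"])

    def test_printed_deterioration_examples(self):
        table = self._table(
            [
                ("Voting", "all", 2019, 7.5),
                ("Voting", "all", 2020, 11.6),
                ("Benchmark", "all", 2019, 11.7),
                ("Benchmark", "all", 2020, 29.9),
            ]
        )
        assert round_half_away(drift_deterioration(table, "Voting", 2019, 2020)) == 55
        assert round_half_away(drift_deterioration(table, "Benchmark", 2019, 2020)) == 156

    def test_equal_mapes_give_zero_change(self):
        table = self._table([("A", "all", 2019, 8.0), ("A", "all", 2020, 8.0)])
        assert drift_deterioration(table, "A", 2019, 2020) == 0.0

    def test_zero_reference_is_missing(self):
        table = self._table([("A", "all", 2019, 0.0), ("A", "all", 2020, 5.0)])
        with pytest.warns(UserWarning):
            assert np.isnan(drift_deterioration(table, "A", 2019, 2020))

    def test_printed_ablation_examples(self):
        table = self._table(
            [
                ("Voting", "proxy_only", 2017, 11.0),
                ("Voting", "all", 2017, 8.4),
                ("Voting", "proxy_only", 2020, 12.4),
                ("Voting", "all", 2020, 11.6),
            ]
        )
        imp17 = ablation_improvement(table, "Voting", "proxy_only", "all", 2017)
        imp20 = ablation_improvement(table, "Voting", "proxy_only", "all", 2020)
        assert round_half_away(imp17) == 31
        assert round_half_away(imp20) == 7

    def test_missing_rows_raise(self):
        table = self._table([("A", "all", 2019, 8.0)])
        with pytest.raises(ConfigurationError):
            drift_deterioration(table, "A", 2019, 2020)
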