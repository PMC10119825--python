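"""Benchmark exactness, ARIMA auto-tuning, regression adapters, structural model."""

import numpy as np
import pandas as pd
import pytest

from ucflow import (
    DailySeries,
    InsufficientHistoryError,
    SeasonalStructural,
    regression_adapter,
)
from ucflow.features import FeatureMatrix
from ucflow.forecasters import (
    ArimaAuto,
    enhanced_persistence,
    inhouse_benchmark,
    persistence,
    structural_seasonal,
)


def _series(values, start="2014-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(pd.Series(np.asarray(values, dtype=float), index=idx))


@pytest.fixture(scope="module")
def three_year_series():
    rng = np.random.default_rng(42)
    return _series(rng.integers(50, 200, size=1200).astype(float))


class TestBenchmarks:
    def test_inhouse_is_five_percent_over_last_year(self, three_year_series):
        s = three_year_series
        dates = pd.date_range(s.start + pd.Timedelta(days=1099), periods=7)
        yhat = inhouse_benchmark(s, dates)
        expected = np.array([1.05 * s.at(d - pd.Timedelta(days=364)) for d in dates])
        np.testing.assert_allclose(yhat, expected, rtol=0, atol=0)

    @pytest.mark.parametrize("past,forecast", [(100.0, 105.0), (0.0, 0.0), (37.0, 38.85)])
    def test_inhouse_worked_examples(self, past, forecast):
        values = np.full(371, 50.0)
        values[0] = past
        s = _series(values)
        d = s.start + pd.Timedelta(days=364)
        assert inhouse_benchmark(s, [d])[0] == pytest.approx(forecast)

    def test_persistence_equals_inhouse_divided_by_uplift(self, three_year_series):
        s = three_year_series
        dates = pd.date_range(s.start + pd.Timedelta(days=1099), periods=7)
        np.testing.assert_allclose(persistence(s, dates), inhouse_benchmark(s, dates) / 1.05)

    def test_persistence_on_constant_series(self):
        s = _series(np.full(800, 83.0))
        dates = pd.date_range(s.start + pd.Timedelta(days=700), periods=7)
        assert (persistence(s, dates) == 83.0).all()

    def test_missing_prior_year_raises(self):
        s = _series(np.full(100, 10.0))
        with pytest.raises(InsufficientHistoryError):
            persistence(s, [s.end + pd.Timedelta(days=1)])

    def test_enhanced_persistence_weighted_mean(self):
        # lags (7, 14, 364, 728, 1092) = (15, 15, 0, 0, 0) -> (75 + 60)/15 = 9
        values = np.zeros(1100)
        target_idx = 1095
        values[target_idx - 7] = 15.0
        values[target_idx - 14] = 15.0
        s = _series(np.concatenate([values, np.zeros(10)]))
        d = s.start + pd.Timedelta(days=target_idx)
        assert enhanced_persistence(s, [d])[0] == pytest.approx(9.0)

    def test_enhanced_persistence_constant_and_degenerate_weights(self, three_year_series):
        s = three_year_series
        d = s.start + pd.Timedelta(days=1150)
        const = _series(np.full(1200, 10.0))
        assert enhanced_persistence(const, [d])[0] == pytest.approx(10.0)
        only_first = enhanced_persistence(s, [d], weights=(1, 0, 0, 0, 0))[0]
        assert only_first == s.at(d - pd.Timedelta(days=7))

    def test_enhanced_persistence_lists_missing_lags(self):
        s = _series(np.full(400, 5.0))
        with pytest.raises(InsufficientHistoryError, match="1092"):
            enhanced_persistence(s, [s.end + pd.Timedelta(days=1)])


class TestArima:
    def test_white_noise_forecasts_near_mean(self):
        rng = np.random.default_rng(0)
        mu, sd, n = 100.0, 5.0, 800
        s = _series(rng.normal(mu, sd, n))
        model = ArimaAuto(max_p=2, max_d=1, max_q=2).fit(s)
        dates = pd.date_range(s.end + pd.Timedelta(days=1), periods=7)
        yhat = model.predict(dates)
        assert np.all(np.abs(yhat - mu) < 3 * sd / np.sqrt(n) + 3 * sd * 0.2 + 3)

    def test_linear_trend_selects_differencing(self):
        s = _series(10.0 + 0.5 * np.arange(600))
        model = ArimaAuto(max_p=1, max_d=2, max_q=1).fit(s)
        assert model.order_ is not None and model.order_[1] >= 1

    def test_refit_is_deterministic(self, three_year_series):
        dates = pd.date_range(three_year_series.end + pd.Timedelta(days=1), periods=7)
        a = ArimaAuto(max_p=1, max_d=1, max_q=1).fit(three_year_series)
        b = ArimaAuto(max_p=1, max_d=1, max_q=1).fit(three_year_series)
        assert a.order_ == b.order_
        np.testing.assert_array_equal(a.predict(dates), b.predict(dates))


def _matrices(n_train=60, n_test=7, p=3, seed=0, fn=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_train + n_test, p))
    if fn is None:
        fn = lambda X: 50 + 10 * X[:, 0] - 5 * X[:, 1]
    y = fn(X)
    idx = pd.date_range("2020-01-01", periods=n_train + n_test, freq="D")
    cols = [f"f{i}" for i in range(p)]
    train = FeatureMatrix(
        frame=pd.DataFrame(X[:n_train], index=idx[:n_train], columns=cols),
        origin_date=idx[n_train - 1],
        feature_set="all",
        target=pd.Series(y[:n_train], index=idx[:n_train]),
    )
    test = FeatureMatrix(
        frame=pd.DataFrame(X[n_train:], index=idx[n_train:], columns=cols),
        origin_date=idx[n_train - 1],
        feature_set="all",
        target=pd.Series(y[n_train:], index=idx[n_train:]),
    )
    return train, test


class TestRegressionAdapter:
    def test_knn_k1_returns_duplicated_row_target(self):
        train, test = _matrices()
        # plant an exact duplicate of the first test row in the training set
        train.frame.iloc[0] = test.frame.iloc[0]
        train.target.iloc[0] = 123.0
        yhat = regression_adapter("knn", train, test, {"n_neighbors": 1})
        assert yhat[0] == pytest.approx(123.0)

    def test_ridge_infinite_penalty_predicts_training_mean(self):
        train, test = _matrices()
        yhat = regression_adapter("ridge", train, test, {"alpha": 1e12})
        np.testing.assert_allclose(yhat, train.target.mean(), rtol=1e-4)

    @pytest.mark.parametrize("kind", ["random_forest", "gradient_boosting", "lightgbm"])
    def test_tree_ensembles_bounded_by_training_targets(self, kind):
        train, test = _matrices(seed=1)
        yhat = regression_adapter(kind, train, test, seed=3)
        assert yhat.min() >= max(train.target.min(), 0.0) - 1e-9
        assert yhat.max() <= train.target.max() + 1e-9

    def test_column_mismatch_is_an_error(self):
        from ucflow import ConfigurationError

        train, test = _matrices()
        test.frame.columns = ["a", "b", "c"]
        with pytest.raises(ConfigurationError, match="mismatch"):
            regression_adapter("ridge", train, test)

    def test_unknown_learner_kind_is_an_error(self):
        from ucflow import ConfigurationError

        train, test = _matrices()
        with pytest.raises(ConfigurationError):
            regression_adapter("perceptron", train, test)

    def test_negative_predictions_clipped_to_zero(self):
        train, test = _matrices(fn=lambda X: -100 + 0 * X[:, 0])
        yhat = regression_adapter("ridge", train, test)
        assert (yhat == 0.0).all()


class TestSeasonalStructural:
    def test_pure_weekly_cycle_reproduced_exactly(self):
        pattern = np.array([90.0, 85, 82, 86, 97, 125, 130])
        idx = pd.date_range("2018-01-01", periods=728, freq="D")
        s = DailySeries(pd.Series(pattern[idx.weekday], index=idx))
        dates = pd.date_range(s.end + pd.Timedelta(days=1), periods=7)
        yhat = structural_seasonal(s, target_dates=dates)
        np.testing.assert_allclose(yhat, pattern[dates.weekday], atol=1e-6)

    def test_additive_shift_moves_forecasts_by_constant(self, three_year_series):
        s = three_year_series
        shifted = DailySeries(s.values + 40.0)
        dates = pd.date_range(s.end + pd.Timedelta(days=1), periods=7)
        a = structural_seasonal(s, target_dates=dates)
        b = structural_seasonal(shifted, target_dates=dates)
        np.testing.assert_allclose(b - a, 40.0, atol=1e-6)

    def test_holiday_indicator_moves_only_holiday_dates(self, three_year_series):
        s = three_year_series
        dates = pd.date_range(s.end + pd.Timedelta(days=1), periods=7)
        holiday = dates[2]
        train_holidays = pd.DatetimeIndex(
            [s.start + pd.Timedelta(days=k) for k in (100, 465, 830)]
        )
        # same training holidays in both fits: coefficients identical, the two
        # predictions differ only through the future date's holiday column
        plain = SeasonalStructural(holidays=train_holidays).fit(s).predict(dates)
        flagged = (
            SeasonalStructural(holidays=list(train_holidays) + [holiday])
            .fit(s)
            .predict(dates)
        )
        mask = dates == holiday
        np.testing.assert_allclose(plain[~mask], flagged[~mask], atol=1e-6)
        assert abs(plain[mask][0] - flagged[mask][0]) > 1e-8
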