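"""The heterogeneous bank of 15 daily patient-flow forecasting methods.

Four benchmarks reproducible by hand arithmetic (the in-house +5% rule, the
naive same-day-last-year persistence, its lag-weighted enhancement, and an
AIC-auto-tuned ARIMA), seven tabular regressors predicting each target day
directly from its own feature row (kNN, NuSVR, ridge, kernel ridge, random
forest and two gradient-boosted tree variants), an additive structural
seasonal model, and — defined in :mod:`ucflow.ensembles` — the Voting,
Stacking and trimmed-Averaging meta-estimators that complete the bank.

Every forecaster follows the same contract: ``fit`` on a training series
and/or feature matrix, then ``predict`` one value per target date.  Negative
raw predictions are clipped to zero since arrivals are counts.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, InsufficientHistoryError
from .features import FeatureMatrix
from .simulate import DailySeries

logger = logging.getLogger(__name__)

__all__ = [
    "Forecaster",
    "InHouseBenchmark",
    "Persistence",
    "EnhancedPersistence",
    "ArimaAuto",
    "RegressionForecaster",
    "SeasonalStructural",
    "regression_adapter",
    "inhouse_benchmark",
    "persistence",
    "enhanced_persistence",
    "structural_seasonal",
    "LEARNER_KINDS",
    "BANK_NAMES",
]

# Canonical bank roster; the last three are meta-estimators from ucflow.ensembles
BANK_NAMES = [
    "Benchmark",
    "Naive",
    "Naive (Enhanced)",
    "ARIMA",
    "kNN",
    "SVR (NU)",
    "Ridge",
    "Kernel Ridge",
    "Random Forest",
    "Gradient Boosting",
    "CatBoost",
    "Prophet",
    "Voting",
    "Stacking",
    "Averaging",
]


class Forecaster:
    """Uniform fit/predict contract for every bank member.

    ``requires`` declares the training input: ``"series"`` (univariate,
    ignores feature ablations), ``"matrix"`` (tabular regressor) or
    ``"ensemble"`` (combines other members' forecasts).
    """

    name: str = "base"
    requires: str = "series"

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def clone(self, seed: int | None = None) -> "Forecaster":
        """Fresh unfitted copy, optionally reseeded."""
        raise NotImplementedError

    def fit(self, series: DailySeries | None = None, matrix: FeatureMatrix | None = None):
        raise NotImplementedError

    def predict(self, target_dates, matrix: FeatureMatrix | None = None) -> np.ndarray:
        raise NotImplementedError

    @staticmethod
    def _clip(yhat: np.ndarray) -> np.ndarray:
        yhat = np.asarray(yhat, dtype=float)
        if not np.isfinite(yhat).all():
            raise RuntimeError("forecaster produced non-finite values")
        return np.clip(yhat, 0.0, None)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(name={self.name!r})"


# ---------------------------------------------------------------------------
# hand-computable benchmarks
# ---------------------------------------------------------------------------

class _SeriesLookup(Forecaster):
    requires = "series"

    def fit(self, series=None, matrix=None):
        if series is None:
            raise ConfigurationError(f"{self.name} requires a training series")
        self._series = series
        return self

    def _lagged(self, target_dates, lag: int) -> np.ndarray:
        dates = pd.DatetimeIndex(target_dates)
        vals = self._series.values.reindex(dates - pd.Timedelta(days=lag))
        if vals.isna().any():
            missing = dates[vals.isna().to_numpy()][0]
            raise InsufficientHistoryError(
                f"{self.name}: no observation {lag} days before {missing.date()}"
            )
        return vals.to_numpy(dtype=float)


class InHouseBenchmark(_SeriesLookup):
    """The clinics' in-house rule: same day last year plus 5%."""

    name = "Benchmark"

    def __init__(self, uplift: float = 1.05, seed: int = 0):
        super().__init__(seed)
        self.uplift = float(uplift)

    def clone(self, seed=None):
        return InHouseBenchmark(self.uplift, self.seed if seed is None else seed)

    def predict(self, target_dates, matrix=None):
        return self._clip(self.uplift * self._lagged(target_dates, 364))


class Persistence(_SeriesLookup):
    """Random-walk persistence: the value from the same day a year earlier."""

    name = "Naive"

    def clone(self, seed=None):
        return Persistence(self.seed if seed is None else seed)

    def predict(self, target_dates, matrix=None):
        return self._clip(self._lagged(target_dates, 364))


class EnhancedPersistence(_SeriesLookup):
    """Weighted mean of the five autoregressive lags, recency-weighted.

    Default weights [5, 4, 3, 2, 1] on lags (7, 14, 364, 728, 1092) days,
    normalised by the weight total.
    """

    name = "Naive (Enhanced)"
    LAGS = (7, 14, 364, 728, 1092)

    def __init__(self, weights: Sequence[float] = (5, 4, 3, 2, 1), seed: int = 0):
        super().__init__(seed)
        if len(weights) != len(self.LAGS):
            raise ConfigurationError("enhanced persistence needs one weight per lag")
        self.weights = tuple(float(w) for w in weights)
        if sum(self.weights) <= 0:
            raise ConfigurationError("enhanced persistence weights must sum to > 0")

    def clone(self, seed=None):
        return EnhancedPersistence(self.weights, self.seed if seed is None else seed)

    def predict(self, target_dates, matrix=None):
        missing = []
        cols = []
        for lag in self.LAGS:
            try:
                cols.append(self._lagged(target_dates, lag))
            except InsufficientHistoryError:
                missing.append(lag)
        if missing:
            raise InsufficientHistoryError(
                f"{self.name}: insufficient history for lags {missing} (days)"
            )
        stacked = np.stack(cols)
        w = np.asarray(self.weights)[:, None]
        return self._clip((w * stacked).sum(axis=0) / w.sum())


# functional forms of the benchmark operations

def inhouse_benchmark(series: DailySeries, target_dates, uplift: float = 1.05) -> np.ndarray:
    return InHouseBenchmark(uplift).fit(series).predict(target_dates)


def persistence(series: DailySeries, target_dates) -> np.ndarray:
    return Persistence().fit(series).predict(target_dates)


def enhanced_persistence(
    series: DailySeries, target_dates, weights: Sequence[float] = (5, 4, 3, 2, 1)
) -> np.ndarray:
    return EnhancedPersistence(weights).fit(series).predict(target_dates)


# ---------------------------------------------------------------------------
# ARIMA with AIC auto-tuning
# ---------------------------------------------------------------------------

class ArimaAuto(Forecaster):
    """Univariate ARIMA, order chosen by minimum AIC over a bounded grid.

    The default grid is p in 0..3, d in 0..2, q in 0..3.  If every candidate
    fails to converge the model falls back to the persistence forecast with a
    logged warning.  No exogenous regressors: this is the classical univariate
    benchmark, and the weekly cycle is carried by the lag features of the
    tabular models instead.
    """

    name = "ARIMA"
    requires = "series"

    def __init__(self, max_p: int = 3, max_d: int = 2, max_q: int = 3, seed: int = 0):
        super().__init__(seed)
        self.max_p, self.max_d, self.max_q = int(max_p), int(max_d), int(max_q)

    def clone(self, seed=None):
        return ArimaAuto(self.max_p, self.max_d, self.max_q, self.seed if seed is None else seed)

    def fit(self, series=None, matrix=None):
        from statsmodels.tsa.arima.model import ARIMA

        if series is None:
            raise ConfigurationError("ARIMA requires a training series")
        self._series = series
        y = series.values.to_numpy(dtype=float)
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for d in range(self.max_d + 1):
                for p in range(self.max_p + 1):
                    for q in range(self.max_q + 1):
                        try:
                            res = ARIMA(y, order=(p, d, q)).fit()
                        except Exception:
                            continue
                        if np.isfinite(res.aic) and (best is None or res.aic < best[0]):
                            best = (res.aic, (p, d, q), res)
        if best is None:
            logger.warning("ARIMA: no candidate converged; falling back to persistence")
            self.order_, self._result = None, None
        else:
            _, self.order_, self._result = best
        return self

    def predict(self, target_dates, matrix=None):
        dates = pd.DatetimeIndex(target_dates)
        if self._result is None:
            return Persistence().fit(self._series).predict(dates)
        steps = (dates[-1] - self._series.end).days
        if steps < 1:
            raise ConfigurationError("ARIMA target dates must follow the training range")
        path = np.asarray(self._result.forecast(steps=steps), dtype=float)
        offsets = np.array([(d - self._series.end).days - 1 for d in dates])
        return self._clip(path[offsets])


# ---------------------------------------------------------------------------
# tabular regressors (direct multi-horizon)
# ---------------------------------------------------------------------------

def _make_learner(kind: str, hyperparameters: Mapping | None, seed: int):
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.kernel_ridge import KernelRidge
    from sklearn.linear_model import LinearRegression, Ridge
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import NuSVR

    hp = dict(hyperparameters or {})
    if kind == "knn":
        return make_pipeline(StandardScaler(), KNeighborsRegressor(**hp))
    if kind == "ridge":
        return make_pipeline(StandardScaler(), Ridge(**hp))
    if kind == "linear":
        return make_pipeline(StandardScaler(), LinearRegression(**hp))
    if kind == "kernel_ridge":
        hp.setdefault("kernel", "rbf")
        return make_pipeline(StandardScaler(), KernelRidge(**hp))
    if kind == "nu_svr":
        return make_pipeline(StandardScaler(), NuSVR(**hp))
    if kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    if kind == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed, **hp)
    if kind == "lightgbm":
        from lightgbm import LGBMRegressor

        hp.setdefault("n_estimators", 200)
        hp.setdefault("verbose", -1)
        return LGBMRegressor(random_state=seed, n_jobs=1, **hp)
    raise ConfigurationError(f"unknown learner kind {kind!r}")


LEARNER_KINDS = (
    "knn",
    "ridge",
    "linear",
    "kernel_ridge",
    "nu_svr",
    "random_forest",
    "gradient_boosting",
    "lightgbm",
)


class RegressionForecaster(Forecaster):
    """Any tabular regressor under the direct multi-horizon strategy.

    One fitted regressor predicts each target day from that day's own feature
    row; because the shortest lag equals the horizon there is no recursive
    error compounding.
    """

    requires = "matrix"

    def __init__(
        self,
        learner_kind: str,
        name: str | None = None,
        hyperparameters: Mapping | None = None,
        seed: int = 0,
    ):
        super().__init__(seed)
        if learner_kind not in LEARNER_KINDS:
            raise ConfigurationError(f"unknown learner kind {learner_kind!r}")
        self.learner_kind = learner_kind
        self.name = name or learner_kind
        self.hyperparameters = dict(hyperparameters or {})

    def clone(self, seed=None):
        return RegressionForecaster(
            self.learner_kind,
            self.name,
            self.hyperparameters,
            self.seed if seed is None else seed,
        )

    def fit(self, series=None, matrix=None):
        if matrix is None or matrix.target is None:
            raise ConfigurationError(f"{self.name} requires a training feature matrix")
        self._columns = matrix.columns
        self._model = _make_learner(self.learner_kind, self.hyperparameters, self.seed)
        self._model.fit(matrix.frame.to_numpy(dtype=float), matrix.target.to_numpy(dtype=float))
        return self

    def predict(self, target_dates, matrix=None):
        if matrix is None:
            raise ConfigurationError(f"{self.name} requires a test feature matrix")
        if matrix.columns != self._columns:
            raise ConfigurationError(
                f"{self.name}: train/test column mismatch "
                f"({self._columns} vs {matrix.columns})"
            )
        frame = matrix.frame.loc[pd.DatetimeIndex(target_dates)]
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper invents feature names for ndarray fits
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            yhat = self._model.predict(frame.to_numpy(dtype=float))
        return self._clip(yhat)


def regression_adapter(
    learner_kind: str,
    feature_matrix_train: FeatureMatrix,
    feature_matrix_test: FeatureMatrix,
    hyperparameters: Mapping | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Functional form: fit ``learner_kind`` on the train matrix, predict the test rows."""
    model = RegressionForecaster(learner_kind, hyperparameters=hyperparameters, seed=seed)
    model.fit(matrix=feature_matrix_train)
    return model.predict(feature_matrix_test.target_dates, feature_matrix_test)


# ---------------------------------------------------------------------------
# additive structural seasonal model
# ---------------------------------------------------------------------------

class SeasonalStructural(Forecaster):
    """Additive decomposable forecaster: trend + yearly + weekly + holidays.

    Least-squares fit of a linear trend, yearly Fourier harmonics, day-of-week
    effects and a public-holiday indicator.  This is the bank's
    Prophet-style member: an auto-fitted additive model robust to trend
    dislocations at the scale of these series.
    """

    name = "Prophet"
    requires = "series"

    def __init__(self, yearly_harmonics: int = 3, holidays=None, seed: int = 0):
        super().__init__(seed)
        self.yearly_harmonics = int(yearly_harmonics)
        self.holidays = set(pd.Timestamp(h) for h in holidays) if holidays is not None else set()

    def clone(self, seed=None):
        return SeasonalStructural(
            self.yearly_harmonics, self.holidays, self.seed if seed is None else seed
        )

    def _design(self, dates: pd.DatetimeIndex) -> np.ndarray:
        t = (dates - self._t0).days.to_numpy(dtype=float) / 365.25
        cols = [np.ones(len(dates)), t]
        doy = dates.dayofyear.to_numpy(dtype=float)
        for k in range(1, self.yearly_harmonics + 1):
            ang = 2.0 * np.pi * k * doy / 365.25
            cols += [np.sin(ang), np.cos(ang)]
        dow = dates.weekday.to_numpy()
        for d in range(6):  # Monday is the reference level
            cols.append((dow == d + 1).astype(float))
        cols.append(np.array([1.0 if d in self.holidays else 0.0 for d in dates]))
        return np.column_stack(cols)

    def fit(self, series=None, matrix=None):
        if series is None:
            raise ConfigurationError("the structural seasonal model requires a training series")
        self._t0 = series.start
        X = self._design(series.dates)
        y = series.values.to_numpy(dtype=float)
        self._coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return self

    def predict(self, target_dates, matrix=None):
        dates = pd.DatetimeIndex(target_dates)
        return self._clip(self._design(dates) @ self._coef)


def structural_seasonal(series: DailySeries, holidays=None, target_dates=None) -> np.ndarray:
    """Functional form: fit the additive model and forecast 7 days past the series end."""
    model = SeasonalStructural(holidays=holidays).fit(series)
    if target_dates is None:
        target_dates = pd.date_range(series.end + pd.Timedelta(days=1), periods=7, freq="D")
    return model.predict(target_dates)
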