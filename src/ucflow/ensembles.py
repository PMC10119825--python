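"""Meta-estimators combining base forecasters: Voting, trimmed Averaging, Stacking.

Voting takes a weighted mean of its bases' daily forecasts (uniform weights by
default).  The Averaging model discards exactly one highest and one lowest
base prediction per day and averages the remainder.  Stacking holds out the
tail of the training range, fits the bases on the head, collects their
out-of-sample forecasts on the tail as meta-features, fits a regularised
linear meta-learner on (base forecasts -> observed arrivals), refits the bases
on the full training range and passes their test-window forecasts through the
meta-learner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .features import FeatureMatrix
from .forecasters import Forecaster, _make_learner
from .simulate import DailySeries

__all__ = [
    "EnsembleSpec",
    "voting_combine",
    "averaging_combine",
    "stacking_fit_predict",
    "VotingForecaster",
    "AveragingForecaster",
    "StackingForecaster",
]


@dataclass
class EnsembleSpec:
    """Declarative description of one meta-estimator."""

    kind: str                              # voting | stacking | averaging
    base_names: Sequence[str]
    weights: Sequence[float] | None = None          # voting only
    meta_learner: str = "ridge"                     # stacking only
    validation_tail_weeks: int = 8                  # stacking only

    def __post_init__(self):
        if self.kind not in ("voting", "stacking", "averaging"):
            raise ConfigurationError(f"unknown ensemble kind {self.kind!r}")
        if self.kind == "voting":
            if self.weights is None:
                self.weights = tuple(1.0 for _ in self.base_names)
            if len(self.weights) != len(self.base_names):
                raise ConfigurationError("voting needs one weight per base")
            if any(w < 0 for w in self.weights):
                raise ConfigurationError("voting weights must be >= 0")
            if sum(self.weights) <= 0:
                raise ConfigurationError("voting weights must sum to > 0")
        if self.kind == "averaging" and len(self.base_names) < 3:
            raise ConfigurationError(
                "averaging needs >= 3 bases (trimming both extremes must leave >= 1)"
            )
        if self.kind == "stacking" and self.validation_tail_weeks < 2:
            raise ConfigurationError("stacking validation tail must be >= 2 weeks")


def voting_combine(base_forecasts, weights=None) -> np.ndarray:
    """Weighted per-day mean of base forecast vectors.

    ``base_forecasts`` is a (n_bases, horizon) array, a sequence of vectors or
    a name->vector mapping (combined in mapping order).
    """
    if isinstance(base_forecasts, Mapping):
        stacked = np.asarray([np.asarray(v, float) for v in base_forecasts.values()])
    else:
        stacked = np.asarray([np.asarray(v, float) for v in base_forecasts])
    if weights is None:
        weights = np.ones(stacked.shape[0])
    w = np.asarray(weights, dtype=float)
    if len(w) != stacked.shape[0]:
        raise ConfigurationError("one weight per base forecast required")
    if w.sum() <= 0:
        raise ConfigurationError("voting weights must sum to > 0")
    return (w[:, None] * stacked).sum(axis=0) / w.sum()


def averaging_combine(base_forecasts) -> np.ndarray:
    """Per-day trimmed mean: drop exactly one max and one min, average the rest.

    Under ties exactly one instance of the extreme value is removed on each
    side.
    """
    if isinstance(base_forecasts, Mapping):
        stacked = np.asarray([np.asarray(v, float) for v in base_forecasts.values()])
    else:
        stacked = np.asarray([np.asarray(v, float) for v in base_forecasts])
    if stacked.shape[0] < 3:
        raise ConfigurationError("averaging needs at least 3 base forecasts")
    ordered = np.sort(stacked, axis=0)
    return ordered[1:-1].mean(axis=0)


def stacking_fit_predict(
    bases: Sequence[Forecaster],
    train_series: DailySeries,
    matrix_for: Callable[[pd.DatetimeIndex], FeatureMatrix] | None,
    test_matrix: FeatureMatrix | None,
    target_dates,
    meta_learner: str = "ridge",
    validation_tail_weeks: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Stacked generalisation over heterogeneous base forecasters.

    ``matrix_for`` builds a training feature matrix for an arbitrary set of
    dates (None if no base needs one).  The meta-training set is formed from
    the bases' genuinely out-of-sample forecasts on the last
    ``validation_tail_weeks`` weeks of the training range.
    """
    if validation_tail_weeks < 2:
        raise ConfigurationError("stacking validation tail must be >= 2 weeks")
    tail_days = 7 * validation_tail_weeks
    if len(train_series) <= tail_days + 7:
        raise ConfigurationError("training range too short to reserve the stacking tail")
    head_end = train_series.end - pd.Timedelta(days=tail_days)
    head = train_series.slice(train_series.start, head_end)
    tail_dates = pd.date_range(head_end + pd.Timedelta(days=1), train_series.end, freq="D")
    target_dates = pd.DatetimeIndex(target_dates)

    def _run(series: DailySeries, dates: pd.DatetimeIndex, predict_matrix) -> np.ndarray:
        cols = []
        for i, base in enumerate(bases):
            model = base.clone(seed=seed + i)
            if model.requires == "matrix":
                if matrix_for is None:
                    raise ConfigurationError(
                        f"stacking base {model.name!r} needs feature matrices"
                    )
                train_dates = series.dates
                model.fit(series, matrix_for(train_dates))
                cols.append(model.predict(dates, predict_matrix))
            else:
                model.fit(series)
                cols.append(model.predict(dates))
        return np.column_stack(cols)

    tail_matrix = matrix_for(tail_dates) if matrix_for is not None else None
    X_meta = _run(head, tail_dates, tail_matrix)
    y_meta = train_series.values.reindex(tail_dates).to_numpy(dtype=float)
    meta = _make_learner(meta_learner, None, seed)
    meta.fit(X_meta, y_meta)

    X_test = _run(train_series, target_dates, test_matrix)
    return np.clip(np.asarray(meta.predict(X_test), dtype=float), 0.0, None)


# ---------------------------------------------------------------------------
# bank-facing forecaster wrappers
# ---------------------------------------------------------------------------

class _CombiningForecaster(Forecaster):
    """Combines the current window's base forecasts; fed by the backtest engine."""

    requires = "ensemble"

    def __init__(self, spec: EnsembleSpec, name: str, seed: int = 0):
        super().__init__(seed)
        self.spec = spec
        self.name = name

    @property
    def base_names(self) -> list[str]:
        return list(self.spec.base_names)

    def fit(self, series=None, matrix=None):
        return self

    def _gather(self, base_forecasts: Mapping[str, np.ndarray]) -> list[np.ndarray]:
        missing = [b for b in self.base_names if b not in base_forecasts]
        if missing:
            raise ConfigurationError(f"{self.name}: missing base forecasts for {missing}")
        return [np.asarray(base_forecasts[b], float) for b in self.base_names]


class VotingForecaster(_CombiningForecaster):
    def __init__(self, spec: EnsembleSpec, seed: int = 0):
        if spec.kind != "voting":
            raise ConfigurationError("VotingForecaster needs a voting spec")
        super().__init__(spec, "Voting", seed)

    def clone(self, seed=None):
        return VotingForecaster(self.spec, self.seed if seed is None else seed)

    def combine(self, base_forecasts: Mapping[str, np.ndarray]) -> np.ndarray:
        return voting_combine(self._gather(base_forecasts), self.spec.weights)


class AveragingForecaster(_CombiningForecaster):
    def __init__(self, spec: EnsembleSpec, seed: int = 0):
        if spec.kind != "averaging":
            raise ConfigurationError("AveragingForecaster needs an averaging spec")
        super().__init__(spec, "Averaging", seed)

    def clone(self, seed=None):
        return AveragingForecaster(self.spec, self.seed if seed is None else seed)

    def combine(self, base_forecasts: Mapping[str, np.ndarray]) -> np.ndarray:
        return averaging_combine(self._gather(base_forecasts))


class StackingForecaster(Forecaster):
    """Bank wrapper around :func:`stacking_fit_predict`.

    Holds unfitted clones of its bases; the backtest engine provides the
    training series, a feature-matrix builder and the test matrix.
    """

    requires = "stacking"

    def __init__(self, spec: EnsembleSpec, bases: Sequence[Forecaster], seed: int = 0):
        if spec.kind != "stacking":
            raise ConfigurationError("StackingForecaster needs a stacking spec")
        super().__init__(seed)
        self.spec = spec
        self.name = "Stacking"
        by_name = {b.name: b for b in bases}
        missing = [n for n in spec.base_names if n not in by_name]
        if missing:
            raise ConfigurationError(f"Stacking: unknown base names {missing}")
        self.bases = [by_name[n] for n in spec.base_names]

    @property
    def base_names(self) -> list[str]:
        return list(self.spec.base_names)

    def clone(self, seed=None):
        return StackingForecaster(self.spec, self.bases, self.seed if seed is None else seed)

    def fit_predict(
        self,
        train_series: DailySeries,
        matrix_for,
        test_matrix: FeatureMatrix | None,
        target_dates,
    ) -> np.ndarray:
        return stacking_fit_predict(
            self.bases,
            train_series,
            matrix_for,
            test_matrix,
            target_dates,
            meta_learner=self.spec.meta_learner,
            validation_tail_weeks=self.spec.validation_tail_weeks,
            seed=self.seed,
        )
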