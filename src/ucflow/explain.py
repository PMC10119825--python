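"""Attribution of fitted bank members, including the Voting ensemble.

A tabular forecaster is attributed directly on its feature row.  The Voting
ensemble is attributed as a single function: the weighted mean of its bases'
outputs, where tabular bases respond to the feature row and purely univariate
bases (ARIMA, the structural seasonal model, the naive rules) contribute a
constant for the explained date — their share therefore appears in the base
value E[f(x)], not in any feature's contribution, since they consume no
feature row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .backtest import MAX_TRAIN_DAYS
from .ensembles import VotingForecaster
from .features import assemble, build_training_matrix
from .forecasters import Forecaster
from .shapley import AttributionResult, shapley_exact, shapley_sampled
from .simulate import DailySeries, ProxyPanel

__all__ = ["attributable_function", "explain_date", "DEFAULT_BACKGROUND_SIZE"]

DEFAULT_BACKGROUND_SIZE = 200


def attributable_function(
    bank: list[Forecaster],
    model_name: str,
    train_series: DailySeries,
    train_matrix,
    target_date: pd.Timestamp,
    seed: int = 0,
):
    """Fit ``model_name`` from the bank and return f(feature rows) for one date.

    For the Voting ensemble, tabular bases are fitted and evaluated per row;
    univariate bases are fitted once and enter as per-date constants.
    """
    by_name = {m.name: m for m in bank}
    if model_name not in by_name:
        raise ConfigurationError(f"model {model_name!r} not in the bank")
    member = by_name[model_name]

    if member.requires == "matrix":
        fitted = member.clone(seed=seed).fit(train_series, train_matrix)

        def f(rows: np.ndarray) -> np.ndarray:
            return np.clip(fitted._model.predict(np.asarray(rows, float)), 0.0, None)

        return f

    if isinstance(member, VotingForecaster):
        weights = np.asarray(member.spec.weights, dtype=float)
        parts = []
        for base_name in member.base_names:
            base = by_name.get(base_name)
            if base is None:
                raise ConfigurationError(f"voting base {base_name!r} not in the bank")
            model = base.clone(seed=seed)
            if model.requires == "matrix":
                model.fit(train_series, train_matrix)
                parts.append(("matrix", model))
            elif model.requires == "series":
                model.fit(train_series)
                const = float(model.predict(pd.DatetimeIndex([target_date]))[0])
                parts.append(("const", const))
            else:
                raise ConfigurationError(
                    f"voting base {base_name!r} cannot be attributed as a function"
                )

        def f(rows: np.ndarray) -> np.ndarray:
            rows = np.asarray(rows, float)
            acc = np.zeros(rows.shape[0])
            for w, (kind, part) in zip(weights, parts):
                if kind == "matrix":
                    acc += w * np.clip(part._model.predict(rows), 0.0, None)
                else:
                    acc += w * part
            return acc / weights.sum()

        return f

    raise ConfigurationError(
        f"model {model_name!r} consumes no feature row and cannot be attributed"
    )


def explain_date(
    series: DailySeries,
    panel: ProxyPanel,
    bank: list[Forecaster],
    target_date,
    model_name: str = "Voting",
    feature_set: str = "all",
    method: str = "exact",
    n_background: int = DEFAULT_BACKGROUND_SIZE,
    n_permutations: int = 500,
    seed: int = 0,
) -> AttributionResult:
    """Explain one date's forecast: fit on the 5-year window before its origin.

    The forecast origin is the last Saturday-aligned position 1-7 days before
    the target, mirroring the weekly backtest cadence; here it is simply taken
    as 7 days before the target so all lags are observed.
    """
    target = pd.Timestamp(target_date)
    origin = target - pd.Timedelta(days=7)
    train_start = max(series.start, origin - pd.Timedelta(days=MAX_TRAIN_DAYS - 1))
    train_series = series.slice(train_start, origin)
    train_matrix = build_training_matrix(
        series.slice(series.start, origin), panel, train_series.dates, feature_set
    )
    test_matrix = assemble(series.slice(series.start, origin), panel, origin, feature_set)
    if target not in test_matrix.frame.index:
        raise ConfigurationError(f"{target.date()} outside the 7-day window after the origin")
    instance = test_matrix.frame.loc[target]

    f = attributable_function(bank, model_name, train_series, train_matrix, target, seed)

    rng = np.random.default_rng(seed)
    n_rows = len(train_matrix.frame)
    take = min(n_background, n_rows)
    idx = rng.choice(n_rows, size=take, replace=False)
    background = train_matrix.frame.iloc[np.sort(idx)]

    if method == "exact":
        return shapley_exact(f, instance, background, instance_date=target)
    if method == "sampled":
        return shapley_sampled(
            f, instance, background, n_permutations=n_permutations, seed=seed,
            instance_date=target,
        )
    raise ConfigurationError("method must be 'exact' or 'sampled'")
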