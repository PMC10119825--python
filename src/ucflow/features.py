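"""Leakage-safe feature construction for 7-day-ahead demand forecasting.

Predictors follow a fixed dictionary: five autoregressive lags of the arrival
series (``lag7d``, ``lag14d`` and the year-multiples ``lag1`` = 364 d,
``lag2`` = 728 d, ``lag3`` = 1092 d), two calendar columns (``week``,
``public_holiday``) and five proxy covariates (``ped_count``, ``flu_percent``,
``covid_level``, ``trends``, ``feels_like``).  Because the shortest lag (7
days) equals the forecast horizon, every lag needed for a 7-day test window is
already observed at the forecast origin, so each target day can be predicted
directly from its own feature row without recursive feedback.

Three ablation variants of the feature set are supported: ``all``,
``autoregressive_only`` and ``proxy_only``.  Whether the calendar columns
travel with the autoregressive set is switchable (they do by default).

Availability rule for test rows: observational proxies (pedestrians, flu,
trends, feels-like) are carried forward from their last value observed at the
origin, while ``covid_level``, ``week`` and ``public_holiday`` are taken as
known for future dates — alert levels are announced policy and the calendar is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, InsufficientHistoryError, StructuralError
from .simulate import DailySeries, ProxyPanel

__all__ = [
    "LAG_COLUMNS",
    "CALENDAR_COLUMNS",
    "PROXY_FEATURES",
    "FEATURE_SETS",
    "FeatureMatrix",
    "build_lags",
    "weekly_to_daily",
    "combine_trends",
    "assemble",
    "build_training_matrix",
    "feature_columns",
]

LAG_COLUMNS: dict[str, int] = {
    "lag7d": 7,
    "lag14d": 14,
    "lag1": 364,
    "lag2": 728,
    "lag3": 1092,
}
CALENDAR_COLUMNS = ["week", "public_holiday"]
PROXY_FEATURES = ["ped_count", "flu_percent", "covid_level", "trends", "feels_like"]
# observational proxies are carried forward past the origin; covid_level is known
CARRY_FORWARD = ["ped_count", "flu_percent", "trends", "feels_like"]
FEATURE_SETS = ("all", "autoregressive_only", "proxy_only")
HORIZON = 7


def feature_columns(feature_set: str, ar_includes_calendar: bool = True) -> list[str]:
    """Predictor columns of one ablation variant, in canonical order."""
    if feature_set == "all":
        return list(LAG_COLUMNS) + CALENDAR_COLUMNS + PROXY_FEATURES
    if feature_set == "autoregressive_only":
        cols = list(LAG_COLUMNS)
        if ar_includes_calendar:
            cols += CALENDAR_COLUMNS
        return cols
    if feature_set == "proxy_only":
        return CALENDAR_COLUMNS + PROXY_FEATURES
    raise ConfigurationError(
        f"unknown feature_set {feature_set!r}; expected one of {FEATURE_SETS}"
    )


@dataclass
class FeatureMatrix:
    """Per-target-date predictor rows, tagged with origin and feature set.

    ``frame`` is indexed by target date; ``target`` holds observed arrivals for
    those dates where known (absent at prediction time).
    """

    frame: pd.DataFrame
    origin_date: pd.Timestamp
    feature_set: str
    target: pd.Series | None = None

    @property
    def target_dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


def _series_values(series) -> pd.Series:
    if isinstance(series, DailySeries):
        return series.values
    s = pd.Series(series).copy()
    s.index = pd.DatetimeIndex(s.index)
    if len(s) > 1:
        steps = np.diff(s.index.values).astype("timedelta64[D]").astype(int)
        if (steps != 1).any():
            raise StructuralError("lag construction requires a gap-free daily series")
    return s


def build_lags(
    series,
    dates,
    lag_days: Mapping[str, int] | Iterable[int] | None = None,
) -> pd.DataFrame:
    """Lagged arrival values for each requested date.

    Returns one column per lag; cells whose lagged date precedes the series
    start are NaN (incomplete history).  ``lag_days`` may be a name->days
    mapping or a plain iterable of day offsets (named ``lag<k>d`` then).
    """
    values = _series_values(series)
    if lag_days is None:
        lags = dict(LAG_COLUMNS)
    elif isinstance(lag_days, Mapping):
        lags = dict(lag_days)
    else:
        lags = {f"lag{int(k)}d": int(k) for k in lag_days}
    dates = pd.DatetimeIndex(dates)
    out = {}
    for name, k in lags.items():
        shifted = dates - pd.Timedelta(days=k)
        out[name] = values.reindex(shifted).to_numpy(dtype=float)
    return pd.DataFrame(out, index=dates)


def weekly_to_daily(weekly: pd.Series, start=None, end=None) -> pd.Series:
    """Broadcast weekly records (tagged by week-start date) to daily values.

    Each of the 7 days from a record's week-start receives that week's value;
    weeks with no record stay missing (no interpolation), as do days before
    the first record.  Overlapping records (starts < 7 days apart) are a
    structural error.
    """
    weekly = pd.Series(weekly).copy()
    weekly.index = pd.DatetimeIndex(weekly.index)
    weekly = weekly.sort_index()
    if weekly.index.has_duplicates:
        raise StructuralError("duplicate week-start dates in weekly records")
    starts = weekly.index
    if len(starts) > 1:
        gaps = np.diff(starts.values).astype("timedelta64[D]").astype(int)
        if (gaps < 7).any():
            bad = starts[int(np.argmax(gaps < 7)) + 1]
            raise StructuralError(f"overlapping weekly records at {bad.date()}")
    start = starts[0] if start is None else pd.Timestamp(start)
    end = (starts[-1] + pd.Timedelta(days=6)) if end is None else pd.Timestamp(end)
    days = pd.date_range(start, end, freq="D")
    out = pd.Series(np.nan, index=days, name=weekly.name)
    for ws, val in weekly.items():
        span = out.index[(out.index >= ws) & (out.index <= ws + pd.Timedelta(days=6))]
        out.loc[span] = val
    return out


def combine_trends(keyword_series: Sequence[pd.Series]) -> pd.Series:
    """Collapse per-keyword search signals into one weekly series.

    Unweighted mean across keywords per week, rescaled so the panel maximum is
    100 (left unscaled if the signal is identically zero).
    """
    if len(keyword_series) < 1:
        raise ConfigurationError("combine_trends needs at least one keyword series")
    frame = pd.concat([pd.Series(s) for s in keyword_series], axis=1)
    combined = frame.mean(axis=1)
    peak = combined.max()
    if peak > 0:
        combined = combined * (100.0 / peak)
    combined.name = "trends"
    return combined


def _panel_rows(panel: ProxyPanel, dates: pd.DatetimeIndex, origin: pd.Timestamp) -> pd.DataFrame:
    """Proxy rows for target dates under the availability rule."""
    rows = panel.frame.reindex(dates).copy()
    observed = panel.frame.loc[:origin]
    for col in CARRY_FORWARD:
        col_obs = observed[col].dropna()
        last = col_obs.iloc[-1] if len(col_obs) else np.nan
        future = dates > origin
        rows.loc[future, col] = last
    return rows


def assemble(
    series: DailySeries,
    panel: ProxyPanel,
    origin_date,
    feature_set: str = "all",
    ar_includes_calendar: bool = True,
    horizon: int = HORIZON,
) -> FeatureMatrix:
    """Build the prediction-time feature rows for origin+1 .. origin+horizon.

    No predictor cell derives from observations after ``origin_date`` except
    ``covid_level`` and the calendar columns, which are known in advance.
    Missing ``flu_percent`` is imputed as 0.0 (prevalence is low when
    unreported).  Observed arrivals for the target dates are attached as
    ``target`` where available.
    """
    origin = pd.Timestamp(origin_date)
    if origin < series.start or origin > series.end:
        raise ConfigurationError(f"origin {origin.date()} outside the series range")
    if origin < panel.dates[0] or origin > panel.dates[-1]:
        raise ConfigurationError(f"origin {origin.date()} outside the panel range")
    dates = pd.date_range(origin + pd.Timedelta(days=1), periods=horizon, freq="D")
    cols = feature_columns(feature_set, ar_includes_calendar)

    parts = []
    if feature_set in ("all", "autoregressive_only"):
        lag_frame = build_lags(series.values.loc[:origin], dates)
        bad = lag_frame.columns[lag_frame.isna().any()].tolist()
        if bad:
            raise InsufficientHistoryError(
                f"origin {origin.date()} lacks history for lag columns {bad}"
            )
        parts.append(lag_frame)
    rows = _panel_rows(panel, dates, origin)
    rows["flu_percent"] = rows["flu_percent"].fillna(0.0)
    parts.append(rows)
    frame = pd.concat(parts, axis=1)[cols]

    target = series.values.reindex(dates)
    target = target if target.notna().all() else None
    return FeatureMatrix(frame=frame, origin_date=origin, feature_set=feature_set, target=target)


def build_training_matrix(
    series: DailySeries,
    panel: ProxyPanel,
    dates,
    feature_set: str = "all",
    ar_includes_calendar: bool = True,
) -> FeatureMatrix:
    """Historical feature rows with targets for fitting tabular regressors.

    Rows use the proxy values actually recorded on each date (all historical
    at training time).  Dates whose lag history is incomplete are dropped for
    lag-bearing feature sets.
    """
    dates = pd.DatetimeIndex(dates)
    cols = feature_columns(feature_set, ar_includes_calendar)
    parts = []
    if feature_set in ("all", "autoregressive_only"):
        parts.append(build_lags(series, dates))
    rows = panel.frame.reindex(dates).copy()
    rows["flu_percent"] = rows["flu_percent"].fillna(0.0)
    parts.append(rows)
    frame = pd.concat(parts, axis=1)[cols]
    target = series.values.reindex(dates)
    keep = frame.notna().all(axis=1) & target.notna()
    frame, target = frame.loc[keep], target.loc[keep]
    if frame.empty:
        raise InsufficientHistoryError(
            f"no training rows with complete {feature_set!r} features in the requested range"
        )
    return FeatureMatrix(
        frame=frame, origin_date=dates[-1], feature_set=feature_set, target=target
    )
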