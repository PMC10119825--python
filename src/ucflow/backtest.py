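"""Expanding-window weekly backtest of the forecaster bank.

The evaluation protocol walks forward in 7-day test windows.  Training data
expand from the series start until they reach a 5-year cap (1826 days), after
which the window rolls.  Every bank member is refit from scratch for every
window, and the whole pass is repeated once per feature-set ablation;
univariate methods ignore the feature set but run in every pass so that
within-window ranks stay comparable across all bank members.

The module follows the model/results convention: :class:`Backtest` is built
from the data and the bank, and its :meth:`Backtest.run` returns a
:class:`BacktestResults` carrying the per-day forecast records together with
metric tables, mean ranks, yearly breakdowns and a ``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, StructuralError
from .bank import default_bank, validate_bank
from .features import FEATURE_SETS, assemble, build_training_matrix
from .forecasters import Forecaster
from .simulate import DailySeries, ProxyPanel

logger = logging.getLogger(__name__)

__all__ = [
    "WindowPlan",
    "make_windows",
    "run_backtest",
    "Backtest",
    "BacktestResults",
    "MAX_TRAIN_DAYS",
    "LONGEST_LAG",
    "REPORT_COLUMNS",
]

MAX_TRAIN_DAYS = 1826      # 5-year training cap
LONGEST_LAG = 1092
REPORT_COLUMNS = ["feature_set", "window_id", "year", "model", "date", "y", "yhat"]


@dataclass(frozen=True)
class WindowPlan:
    """One weekly test window and its training range."""

    window_id: int
    train_start: pd.Timestamp
    train_end: pd.Timestamp
    test_start: pd.Timestamp
    test_end: pd.Timestamp

    @property
    def year(self) -> int:
        return int(self.test_start.year)

    @property
    def test_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.test_start, self.test_end, freq="D")


def make_windows(
    data_start,
    first_test_date,
    data_end,
    max_train_years: int = 5,
) -> list[WindowPlan]:
    """Plan the weekly windows: test_start = first_test_date + 7k.

    Only windows whose full 7 days fall on or before ``data_end`` are
    included.  ``train_start`` is capped at ``max_train_years`` (counted as
    365.25-day years, i.e. 1826 days for the default 5).
    """
    data_start = pd.Timestamp(data_start)
    first = pd.Timestamp(first_test_date)
    data_end = pd.Timestamp(data_end)
    if not (data_start < first <= data_end):
        raise ConfigurationError("need data_start < first_test_date <= data_end")
    if (first - data_start).days < 7:
        raise ConfigurationError("fewer than 7 days of training before the first test window")
    if (first - data_start).days < LONGEST_LAG:
        warnings.warn(
            f"only {(first - data_start).days} days precede the first test window; "
            f"the longest autoregressive lag ({LONGEST_LAG} d) will be unavailable",
            stacklevel=2,
        )
    cap = round(max_train_years * 365.25)
    windows = []
    k = 0
    while True:
        test_start = first + pd.Timedelta(days=7 * k)
        test_end = test_start + pd.Timedelta(days=6)
        if test_end > data_end:
            break
        train_end = test_start - pd.Timedelta(days=1)
        train_start = max(data_start, test_start - pd.Timedelta(days=cap))
        windows.append(WindowPlan(k, train_start, train_end, test_start, test_end))
        k += 1
    return windows


def _stage_seed(master: int, fs_idx: int, window_id: int, model_idx: int) -> int:
    ss = np.random.SeedSequence([int(master), fs_idx, window_id, model_idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_backtest(
    series: DailySeries,
    panel: ProxyPanel,
    bank: Sequence[Forecaster] | None = None,
    windows: Sequence[WindowPlan] | None = None,
    feature_sets: Sequence[str] = FEATURE_SETS,
    seed: int = 0,
    ar_includes_calendar: bool = True,
    failure_limit: float = 0.05,
) -> "BacktestResults":
    """Execute the full protocol; see :class:`Backtest` for the object form.

    Per feature set x window x bank member: refit on the window's training
    slice, forecast the 7 test days, record forecasts against observations.
    Failed fits are logged and recorded as missing; if any model fails in more
    than ``failure_limit`` of its cells the run aborts with a per-model
    summary.
    """
    if bank is None:
        holidays = panel.frame.index[panel.frame["public_holiday"] == 1]
        bank = default_bank(seed=seed, holidays=holidays)
    validate_bank(bank)
    for fs in feature_sets:
        if fs not in FEATURE_SETS:
            raise ConfigurationError(f"unknown feature set {fs!r}")
    if windows is None:
        first = series.start + pd.Timedelta(days=LONGEST_LAG)
        windows = make_windows(series.start, first, series.end)
    if not windows:
        raise ConfigurationError("no complete test windows in the requested range")
    lo, hi = windows[0].train_start, windows[-1].test_end
    if series.start > lo or series.end < hi or panel.dates[0] > lo or panel.dates[-1] < hi:
        raise ConfigurationError("series/panel do not cover all window ranges")

    needs_matrix = any(m.requires in ("matrix", "stacking") for m in bank)
    rows: list[tuple] = []
    failures: dict[str, int] = {m.name: 0 for m in bank}
    cells: dict[str, int] = {m.name: 0 for m in bank}
    univariate_cache: dict[tuple[int, str], np.ndarray] = {}

    for fs_idx, fs in enumerate(feature_sets):
        for win in windows:
            train_series = series.slice(win.train_start, win.train_end)
            train_dates = train_series.dates
            test_dates = win.test_dates
            y_obs = series.values.reindex(test_dates).to_numpy(dtype=float)

            train_matrix = test_matrix = None
            matrix_error: Exception | None = None
            if needs_matrix:
                try:
                    train_matrix = build_training_matrix(
                        series.slice(series.start, win.train_end), panel, train_dates,
                        fs, ar_includes_calendar,
                    )
                    test_matrix = assemble(
                        series.slice(series.start, win.train_end), panel, win.train_end,
                        fs, ar_includes_calendar,
                    )
                except Exception as exc:  # noqa: BLE001 - recorded per model below
                    matrix_error = exc

            def matrix_for(dates, _fs=fs, _win=win):
                return build_training_matrix(
                    series.slice(series.start, _win.train_end), panel, dates,
                    _fs, ar_includes_calendar,
                )

            base_forecasts: dict[str, np.ndarray] = {}
            for m_idx, member in enumerate(bank):
                cells[member.name] += 1
                model = member.clone(seed=_stage_seed(seed, fs_idx, win.window_id, m_idx))
                try:
                    if model.requires == "series":
                        key = (win.window_id, model.name)
                        if key in univariate_cache:
                            yhat = univariate_cache[key]
                        else:
                            yhat = model.fit(train_series).predict(test_dates)
                            univariate_cache[key] = yhat
                    elif model.requires == "matrix":
                        if matrix_error is not None:
                            raise matrix_error
                        yhat = model.fit(train_series, train_matrix).predict(
                            test_dates, test_matrix
                        )
                    elif model.requires == "ensemble":
                        yhat = model.combine(base_forecasts)
                    elif model.requires == "stacking":
                        if matrix_error is not None and any(
                            b.requires == "matrix" for b in model.bases
                        ):
                            raise matrix_error
                        yhat = model.fit_predict(
                            train_series, matrix_for, test_matrix, test_dates
                        )
                    else:  # pragma: no cover - contract guard
                        raise ConfigurationError(
                            f"unknown requirement {model.requires!r} for {model.name}"
                        )
                except Exception as exc:  # noqa: BLE001 - logged, never silently dropped
                    failures[member.name] += 1
                    logger.warning(
                        "fit failure: model=%s feature_set=%s window=%d: %s",
                        member.name, fs, win.window_id, exc,
                    )
                    continue
                yhat = np.asarray(yhat, dtype=float)
                if yhat.shape != test_dates.shape:
                    failures[member.name] += 1
                    logger.warning(
                        "wrong forecast length from %s in window %d", member.name, win.window_id
                    )
                    continue
                base_forecasts[member.name] = yhat
                for d, yo, yh in zip(test_dates, y_obs, yhat):
                    rows.append((fs, win.window_id, win.year, member.name, d, yo, yh))

    over = {
        name: failures[name] / cells[name]
        for name in failures
        if cells[name] and failures[name] / cells[name] > failure_limit
    }
    if over:
        summary = ", ".join(f"{n}: {100 * f:.1f}% failed" for n, f in sorted(over.items()))
        raise RuntimeError(f"backtest aborted, failure limit exceeded ({summary})")

    records = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return BacktestResults(
        records=records,
        windows=list(windows),
        model_names=[m.name for m in bank],
        feature_sets=list(feature_sets),
        seed=seed,
        failures=failures,
    )


class Backtest:
    """Expanding-window backtest study of a forecaster bank on one clinic.

    Parameters mirror :func:`run_backtest`; :meth:`run` executes the protocol
    and returns a :class:`BacktestResults`.
    """

    def __init__(
        self,
        series: DailySeries,
        panel: ProxyPanel,
        bank: Sequence[Forecaster] | None = None,
        windows: Sequence[WindowPlan] | None = None,
        feature_sets: Sequence[str] = FEATURE_SETS,
        ar_includes_calendar: bool = True,
    ):
        self.series = series
        self.panel = panel
        self.bank = bank
        self.windows = windows
        self.feature_sets = list(feature_sets)
        self.ar_includes_calendar = ar_includes_calendar

    def run(self, seed: int = 0) -> "BacktestResults":
        return run_backtest(
            self.series,
            self.panel,
            bank=self.bank,
            windows=self.windows,
            feature_sets=self.feature_sets,
            seed=seed,
            ar_includes_calendar=self.ar_includes_calendar,
        )


class BacktestResults:
    """Per-day forecast records plus the evaluation surface.

    ``records`` has one row per (feature_set, window, model, day):
    columns ``feature_set, window_id, year, model, date, y, yhat``.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        windows: list[WindowPlan],
        model_names: list[str],
        feature_sets: list[str],
        seed: int,
        failures: Mapping[str, int],
    ):
        self.records = records
        self.windows = windows
        self.model_names = model_names
        self.feature_sets = feature_sets
        self.seed = seed
        self.failures = dict(failures)

    # evaluation delegates live in ucflow.metrics to keep one surface per module
    def metric_table(self, by_year: bool = False) -> pd.DataFrame:
        from .metrics import metric_table

        return metric_table(self.records, by_year=by_year)

    def mean_ranks(self) -> pd.DataFrame:
        from .metrics import mean_ranks

        return mean_ranks(self.records)

    def yearly_breakdown(self) -> pd.DataFrame:
        from .metrics import yearly_breakdown

        return yearly_breakdown(self.records)

    def aligned(self, model: str, feature_set: str = "all", year: int | None = None):
        """Chronologically aligned forecasts of one model (for U / DM tests)."""
        from .metrics import AlignedForecasts

        sub = self.records
        sub = sub[(sub["model"] == model) & (sub["feature_set"] == feature_set)]
        if year is not None:
            sub = sub[sub["year"] == year]
        if sub.empty:
            raise ConfigurationError(f"no records for model {model!r} / {feature_set!r}")
        sub = sub.sort_values("date")
        return AlignedForecasts(
            y=sub["y"].to_numpy(float),
            yhat=sub["yhat"].to_numpy(float),
            timestamps=pd.DatetimeIndex(sub["date"]),
        )

    def summary(self) -> str:
        """Human-readable study summary (overall MAPE table per feature set)."""
        table = self.metric_table().round(2)
        lines = [
            "Expanding-window backtest",
            f"  windows: {len(self.windows)} "
            f"({self.windows[0].test_start.date()} .. {self.windows[-1].test_end.date()})",
            f"  models: {len(self.model_names)}; feature sets: {', '.join(self.feature_sets)}",
        ]
        failed = {k: v for k, v in self.failures.items() if v}
        if failed:
            lines.append(f"  fit failures: {failed}")
        lines.append("")
        lines.append(table.to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        out = self.records.copy()
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BacktestResults":
        records = pd.read_csv(path, parse_dates=["date"])
        missing = [c for c in REPORT_COLUMNS if c not in records.columns]
        if missing:
            raise StructuralError(f"report CSV missing columns {missing}")
        return cls(
            records=records,
            windows=[],
            model_names=sorted(records["model"].unique().tolist()),
            feature_sets=sorted(records["feature_set"].unique().tolist()),
            seed=-1,
            failures={},
        )
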