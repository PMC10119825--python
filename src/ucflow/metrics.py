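"""Forecast evaluation: error metrics, Theil's U, Diebold-Mariano, ranks, drift.

MAPE is the primary accuracy measure::

    MAPE = (100/T) * sum_t | (yhat_t - y_t) / y_t |

with RMSE and MAE as companions.  Theil's U relates a model's one-step errors
to the naive last-value forecast's (U < 1 beats persistence)::

    U = sqrt( sum_t ((yhat_{t+1} - y_{t+1}) / y_t)^2
            / sum_t ((y_{t+1} - y_t) / y_t)^2 )

The Diebold-Mariano test compares two forecast sequences' expected loss with
an autocorrelation-robust variance (rectangular kernel truncated at the
forecast horizon minus one) and the Harvey small-sample correction, with
p-values from the t distribution on T-1 degrees of freedom.

Mean ranks summarise the bank: within each weekly window models are ranked by
window MAPE (1 = best, average ranks under ties) and the ranks are averaged
over windows.  Yearly breakdowns, the year-over-year MAPE-deterioration
statistic and the feature-ablation improvement statistic complete the
surface.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigurationError, DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedForecasts",
    "mape",
    "rmse",
    "mae",
    "theils_u",
    "dm_test",
    "mean_ranks",
    "metric_table",
    "yearly_breakdown",
    "drift_deterioration",
    "ablation_improvement",
    "round_half_away",
]


@dataclass
class AlignedForecasts:
    """Date-aligned observation/forecast pairs."""

    y: np.ndarray
    yhat: np.ndarray
    timestamps: pd.DatetimeIndex | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.yhat = np.asarray(self.yhat, dtype=float)
        if self.y.shape != self.yhat.shape or self.y.ndim != 1 or len(self.y) < 1:
            raise ConfigurationError("y and yhat must be equal-length 1-d arrays, T >= 1")

    @property
    def T(self) -> int:
        return len(self.y)


def _coerce(a, yhat=None) -> AlignedForecasts:
    if isinstance(a, AlignedForecasts):
        return a
    return AlignedForecasts(np.asarray(a, float), np.asarray(yhat, float))


def mape(a, yhat=None, zero_policy: str = "exclude") -> float:
    """Mean absolute percentage error, in percent.

    Pairs with ``y_t == 0`` are excluded with a logged count under the default
    policy (``zero_policy="raise"`` turns them into an error instead).
    """
    af = _coerce(a, yhat)
    zeros = af.y == 0
    if zeros.any():
        if zero_policy == "raise":
            raise DegenerateInputError(f"{int(zeros.sum())} observations are zero")
        logger.warning("MAPE: excluding %d zero-valued observations", int(zeros.sum()))
    y, f = af.y[~zeros], af.yhat[~zeros]
    if len(y) == 0:
        raise DegenerateInputError("no non-zero observations for MAPE")
    return float(100.0 * np.mean(np.abs((f - y) / y)))


def rmse(a, yhat=None) -> float:
    """Root mean square error (patients/day)."""
    af = _coerce(a, yhat)
    return float(np.sqrt(np.mean((af.yhat - af.y) ** 2)))


def mae(a, yhat=None) -> float:
    """Mean absolute error (patients/day)."""
    af = _coerce(a, yhat)
    return float(np.mean(np.abs(af.yhat - af.y)))


def theils_u(a, yhat=None) -> float:
    """Theil's U against one-step persistence, on chronologically ordered pairs.

    Returns NaN with a warning when the denominator vanishes (constant
    observations).
    """
    af = _coerce(a, yhat)
    if af.T < 2:
        raise ConfigurationError("Theil's U needs at least two aligned pairs")
    y, f = af.y, af.yhat
    base = y[:-1]
    if (base == 0).any():
        raise DegenerateInputError("Theil's U undefined: zero observation in the base terms")
    num = np.sum(((f[1:] - y[1:]) / base) ** 2)
    den = np.sum(((y[1:] - y[:-1]) / base) ** 2)
    if den == 0:
        warnings.warn("Theil's U undefined on constant observations; returning NaN",
                      stacklevel=2)
        return float("nan")
    return float(np.sqrt(num / den))


def dm_test(
    a_model,
    a_ref,
    horizon: int = 7,
    loss: str = "squared",
) -> tuple[float, float]:
    """Diebold-Mariano comparison of two forecast sequences on the same dates.

    Negative statistics favour the first (model) sequence.  The loss
    differential's long-run variance uses autocovariances up to lag
    ``horizon - 1``; the Harvey small-sample correction rescales the statistic
    and the p-value is two-sided from t(T-1).
    """
    am, ar = _coerce(a_model), _coerce(a_ref)
    if am.T != ar.T:
        raise ConfigurationError("both forecast sequences must align on the same dates")
    if am.timestamps is not None and ar.timestamps is not None:
        if not am.timestamps.equals(ar.timestamps):
            raise ConfigurationError("both forecast sequences must align on the same dates")
    T, h = am.T, int(horizon)
    if T <= h:
        raise ConfigurationError("need more forecasts than the horizon")
    if loss == "squared":
        d = (am.yhat - am.y) ** 2 - (ar.yhat - ar.y) ** 2
    elif loss == "absolute":
        d = np.abs(am.yhat - am.y) - np.abs(ar.yhat - ar.y)
    else:
        raise ConfigurationError("loss must be 'squared' or 'absolute'")
    if np.allclose(d, d[0]):
        raise DegenerateInputError(
            "zero-variance loss differential (identical forecasts?); DM undefined"
        )
    dbar = d.mean()
    dc = d - dbar
    gamma0 = float(dc @ dc) / T
    lrv = gamma0
    for k in range(1, h):
        gk = float(dc[k:] @ dc[:-k]) / T
        lrv += 2.0 * gk
    if lrv <= 0:
        warnings.warn("non-positive long-run variance estimate; falling back to gamma_0",
                      stacklevel=2)
        lrv = gamma0
    dm = dbar / math.sqrt(lrv / T)
    harvey = math.sqrt((T + 1 - 2 * h + h * (h - 1) / T) / T)
    stat = harvey * dm
    p = float(2.0 * stats.t.sf(abs(stat), df=T - 1))
    return float(stat), p


# ---------------------------------------------------------------------------
# report-level aggregation
# ---------------------------------------------------------------------------

def _window_mape(records: pd.DataFrame) -> pd.DataFrame:
    """Per (feature_set, window_id, model) MAPE over the window's 7 days."""
    def _m(g: pd.DataFrame) -> float:
        return mape(g["y"].to_numpy(), g["yhat"].to_numpy())

    out = (
        records.groupby(["feature_set", "window_id", "model"], sort=False)
        .apply(_m, include_groups=False)
        .rename("window_mape")
        .reset_index()
    )
    return out


def _window_ranks(records: pd.DataFrame) -> pd.DataFrame:
    wm = _window_mape(records)
    wm["rank"] = wm.groupby(["feature_set", "window_id"])["window_mape"].rank(
        method="average", ascending=True
    )
    return wm


def mean_ranks(records: pd.DataFrame, feature_set: str | None = None) -> pd.DataFrame:
    """Per-model mean of within-window MAPE ranks (1 = best).

    Windows missing a model are excluded from that model's mean (and logged).
    Returns columns ``feature_set, model, mean_rank, n_windows``.
    """
    sub = records if feature_set is None else records[records["feature_set"] == feature_set]
    ranked = _window_ranks(sub)
    counts = ranked.groupby(["feature_set", "model"])["window_id"].nunique()
    total = ranked.groupby("feature_set")["window_id"].nunique()
    for (fs, model), n in counts.items():
        if n < total[fs]:
            logger.warning(
                "mean_ranks: %s missing from %d windows in %s", model, total[fs] - n, fs
            )
    out = (
        ranked.groupby(["feature_set", "model"], sort=False)
        .agg(mean_rank=("rank", "mean"), n_windows=("window_id", "nunique"))
        .reset_index()
    )
    return out


def metric_table(records: pd.DataFrame, by_year: bool = False) -> pd.DataFrame:
    """MAPE/RMSE/MAE (+/- window-MAPE spread) and mean rank per model.

    With ``by_year`` the table is keyed by the calendar year of each window's
    test start (a window straddling Dec 31 counts to its start year);
    otherwise ``period`` is ``"overall"``.  MAPE is computed over all
    forecast-observation pairs of the cell; ``mape_sd`` is the standard
    deviation of per-window MAPE inside the cell (the "+/-" of a summary
    table); ``rank`` is the mean of within-window ranks.
    """
    keys = ["feature_set", "year"] if by_year else ["feature_set"]
    ranked = _window_ranks(records)
    if by_year:
        years = records[["feature_set", "window_id", "year"]].drop_duplicates()
        ranked = ranked.merge(years, on=["feature_set", "window_id"])

    def _cell(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "MAPE": mape(g["y"].to_numpy(), g["yhat"].to_numpy()),
                "RMSE": rmse(g["y"].to_numpy(), g["yhat"].to_numpy()),
                "MAE": mae(g["y"].to_numpy(), g["yhat"].to_numpy()),
            }
        )

    acc = (
        records.groupby(keys + ["model"], sort=False)
        .apply(_cell, include_groups=False)
        .reset_index()
    )
    spread = (
        ranked.groupby(keys + ["model"], sort=False)
        .agg(mape_sd=("window_mape", "std"), rank=("rank", "mean"))
        .reset_index()
    )
    out = acc.merge(spread, on=keys + ["model"])
    if not by_year:
        out.insert(1, "period", "overall")
    else:
        out = out.rename(columns={"year": "period"})
    return out.sort_values(["feature_set", "MAPE"]).reset_index(drop=True)


def yearly_breakdown(records: pd.DataFrame) -> pd.DataFrame:
    """Metric table keyed by calendar year of each window's test start."""
    return metric_table(records, by_year=True)


def round_half_away(x: float) -> int:
    """Round half away from zero, matching printed integer percentages."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def _lookup_mape(
    table: pd.DataFrame, model: str, period, feature_set: str | None
) -> float:
    sub = table[table["model"] == model]
    if feature_set is not None and "feature_set" in table.columns:
        sub = sub[sub["feature_set"] == feature_set]
    if "period" in table.columns:
        sub = sub[sub["period"] == period]
    elif "year" in table.columns:
        sub = sub[sub["year"] == period]
    if len(sub) != 1:
        raise ConfigurationError(
            f"expected exactly one row for model={model!r}, period={period!r} "
            f"(found {len(sub)})"
        )
    return float(sub["MAPE"].iloc[0])


def drift_deterioration(
    metric_table: pd.DataFrame,
    model: str,
    year_a,
    year_b,
    feature_set: str | None = None,
) -> float:
    """Year-over-year % change in MAPE: 100 * (MAPE_b - MAPE_a) / MAPE_a.

    Positive values mean the accuracy deteriorated from ``year_a`` to
    ``year_b`` (the concept-drift signature).  Display-round with
    :func:`round_half_away`.  Returns NaN when MAPE_a is zero.
    """
    a = _lookup_mape(metric_table, model, year_a, feature_set)
    b = _lookup_mape(metric_table, model, year_b, feature_set)
    if a == 0:
        warnings.warn("deterioration undefined for zero reference MAPE", stacklevel=2)
        return float("nan")
    return 100.0 * (b - a) / a


def ablation_improvement(
    metric_table: pd.DataFrame,
    model: str,
    set_a: str,
    set_b: str,
    year,
) -> float:
    """% improvement of feature set ``set_b`` over ``set_a`` for one year.

    Computed as 100 * (MAPE_a - MAPE_b) / MAPE_b, i.e. relative to the better
    (reference) set's error.  Returns NaN on a zero denominator.
    """
    a = _lookup_mape(metric_table, model, year, set_a)
    b = _lookup_mape(metric_table, model, year, set_b)
    if b == 0:
        warnings.warn("improvement undefined for zero reference MAPE", stacklevel=2)
        return float("nan")
    return 100.0 * (a - b) / b
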