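"""CSV input/output for demand series and proxy panels.

Schemas (comma-separated, UTF-8, header row, ISO-8601 dates, empty field =
missing): a series file has columns ``date,arrivals``; a panel file has
``date`` plus the proxy feature dictionary ``ped_count,flu_percent,
covid_level,trends,feels_like,public_holiday,week``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .simulate import PROXY_COLUMNS, DailySeries, ProxyPanel, StructuralError

__all__ = ["write_series", "load_series", "write_panel", "load_panel", "load_inputs"]


def write_series(series: DailySeries, path) -> None:
    out = series.to_frame()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_panel(panel: ProxyPanel, path) -> None:
    out = panel.to_frame()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _read(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path.name}: unparseable date ({exc})") from exc
    dup = frame["date"].duplicated()
    if dup.any():
        line = int(np.argmax(dup.to_numpy())) + 2  # header is line 1
        raise ValidationError(
            f"{path.name}:{line}: duplicate date {frame['date'][dup].iloc[0].date()}"
        )
    return frame


def load_series(path, clinic_id: str | None = None) -> DailySeries:
    """Load and validate a daily arrivals CSV (gap-free, non-negative)."""
    frame = _read(path, ["date", "arrivals"])
    values = pd.Series(
        frame["arrivals"].to_numpy(dtype=float), index=frame["date"], name="arrivals"
    )
    if values.isna().any():
        line = int(np.argmax(values.isna().to_numpy())) + 2
        raise ValidationError(f"{Path(path).name}:{line}: missing arrivals value")
    try:
        return DailySeries(values, clinic_id=clinic_id or Path(path).stem)
    except StructuralError as exc:
        raise ValidationError(f"{Path(path).name}: {exc}") from exc


def load_panel(path) -> ProxyPanel:
    """Load and validate a proxy panel CSV against the feature dictionary.

    Range violations cite the offending constraint (e.g. covid_level must lie
    in 1-4).
    """
    frame = _read(path, ["date"] + PROXY_COLUMNS)
    lev = frame["covid_level"]
    bad = ~lev.isin([1, 2, 3, 4])
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + 2
        raise ValidationError(
            f"{Path(path).name}:{line}: covid_level {lev[bad].iloc[0]} "
            "violates the 1-4 alert-level range"
        )
    try:
        return ProxyPanel(frame.set_index("date"))
    except StructuralError as exc:
        raise ValidationError(f"{Path(path).name}: {exc}") from exc


def load_inputs(series_path, panel_path) -> tuple[DailySeries, ProxyPanel]:
    """Load a (series, panel) pair and check they cover the same dates."""
    series = load_series(series_path)
    panel = load_panel(panel_path)
    if series.start != panel.dates[0] or series.end != panel.dates[-1]:
        raise ValidationError(
            f"series covers {series.start.date()}..{series.end.date()} but panel "
            f"covers {panel.dates[0].date()}..{panel.dates[-1].date()}"
        )
    return series, panel
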