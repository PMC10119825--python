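"""Shapley-value attribution for tabular forecasters.

Attribution answers, for a single forecast, how much each feature pushed the
prediction above or below the background expectation E[f(x)].  The value
function is interventional: a coalition S is evaluated as the mean model
output over the background rows with the instance's values spliced in on S.
The exact estimator enumerates all 2^p coalitions and is the package's
correctness oracle; the permutation-sampling estimator scales to larger p and
reports per-feature Monte-Carlo standard errors, with the efficiency residual
distributed uniformly so the additivity identity

    base_value + sum_i phi_i = prediction

holds for every attribution.  Global-importance and pairwise-dependence
extractions emit plot-ready data (no rendered figures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError

__all__ = [
    "AttributionResult",
    "shapley_exact",
    "shapley_sampled",
    "global_importance",
    "dependence_interaction",
]

MAX_EXACT_FEATURES = 15


@dataclass
class AttributionResult:
    """One explained forecast: per-feature contributions in patients/day."""

    feature_names: list[str]
    phi: np.ndarray
    base_value: float          # E[f(x)] over the background rows
    prediction: float
    method: str                # "exact" | "sampled"
    instance: np.ndarray
    n_background: int
    instance_date: object | None = None
    n_permutations: int | None = None
    standard_errors: np.ndarray | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "feature": self.feature_names,
                "value": self.instance,
                "phi": self.phi,
            }
        )
        out["base_value"] = self.base_value
        out["prediction"] = self.prediction
        if self.standard_errors is not None:
            out["phi_se"] = self.standard_errors
        return out


def _as_matrix(rows) -> np.ndarray:
    arr = np.asarray(rows, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def _prep(model, instance_row, background_rows):
    if hasattr(instance_row, "to_numpy"):
        names = list(instance_row.index) if isinstance(instance_row, pd.Series) else None
        x = instance_row.to_numpy(dtype=float).ravel()
    else:
        names, x = None, np.asarray(instance_row, dtype=float).ravel()
    if isinstance(background_rows, pd.DataFrame):
        names = names or list(background_rows.columns)
        bg = background_rows.to_numpy(dtype=float)
    else:
        bg = _as_matrix(background_rows)
    if bg.shape[0] < 1:
        raise ConfigurationError("background set must be non-empty")
    if bg.shape[1] != x.size:
        raise ConfigurationError("instance and background disagree on feature count")
    if names is None:
        names = [f"x{i}" for i in range(x.size)]
    f = model.predict if hasattr(model, "predict") else model
    return f, x, bg, names


def shapley_exact(model, instance_row, background_rows, instance_date=None) -> AttributionResult:
    """Exact interventional Shapley values by full coalition enumeration.

    Feasible for p <= 15 features (2^p coalition evaluations, each averaged
    over the background).  ``model`` is anything with ``predict(X)`` (or a
    bare callable on row matrices).
    """
    f, x, bg, names = _prep(model, instance_row, background_rows)
    p = x.size
    if p > MAX_EXACT_FEATURES:
        raise ConfigurationError(
            f"{p} features exceed the exact enumeration bound "
            f"({MAX_EXACT_FEATURES}); use shapley_sampled"
        )
    n_bg = bg.shape[0]

    # v[mask] = mean_b f(x on mask, b elsewhere)
    v = np.empty(1 << p)
    for mask in range(1 << p):
        rows = bg.copy()
        for i in range(p):
            if mask >> i & 1:
                rows[:, i] = x[i]
        v[mask] = float(np.mean(f(rows)))

    fact = [math.factorial(k) for k in range(p + 1)]
    phi = np.zeros(p)
    for mask in range(1 << p):
        s = bin(mask).count("1")
        w = fact[s] * fact[p - s - 1] / fact[p]
        for i in range(p):
            if not (mask >> i & 1):
                phi[i] += w * (v[mask | (1 << i)] - v[mask])

    return AttributionResult(
        feature_names=names,
        phi=phi,
        base_value=float(v[0]),
        prediction=float(v[(1 << p) - 1]),
        method="exact",
        instance=x,
        n_background=n_bg,
        instance_date=instance_date,
    )


def shapley_sampled(
    model,
    instance_row,
    background_rows,
    n_permutations: int = 200,
    seed: int = 0,
    instance_date=None,
) -> AttributionResult:
    """Permutation-sampling Shapley estimator with enforced efficiency.

    For each sampled feature ordering the marginal contributions of walking
    from the all-background to the all-instance configuration are accumulated;
    per-feature Monte-Carlo standard errors come from the spread across
    permutations.  The (small) efficiency residual is spread uniformly across
    features so additivity holds exactly.
    """
    if n_permutations < 10:
        raise ConfigurationError("need at least 10 permutations")
    f, x, bg, names = _prep(model, instance_row, background_rows)
    p = x.size
    n_bg = bg.shape[0]
    rng = np.random.default_rng(seed)

    base_value = float(np.mean(f(bg)))
    prediction = float(np.asarray(f(x[None, :])).ravel()[0])

    contrib = np.zeros((n_permutations, p))
    for r in range(n_permutations):
        order = rng.permutation(p)
        rows = bg.copy()
        prev = float(np.mean(f(rows)))
        for i in order:
            rows[:, i] = x[i]
            cur = float(np.mean(f(rows)))
            contrib[r, i] = cur - prev
            prev = cur
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / math.sqrt(n_permutations)

    residual = (prediction - base_value) - phi.sum()
    phi = phi + residual / p

    return AttributionResult(
        feature_names=names,
        phi=phi,
        base_value=base_value,
        prediction=prediction,
        method="sampled",
        instance=x,
        n_background=n_bg,
        instance_date=instance_date,
        n_permutations=n_permutations,
        standard_errors=se,
        seed=seed,
    )


def global_importance(attributions: list[AttributionResult]) -> pd.DataFrame:
    """Rank features by mean |phi| over a set of attributions.

    Returns one row per feature with ``mean_abs_phi`` (the ranking key),
    ``mean_phi``, and the per-instance (feature value, phi) pairs needed to
    render a beeswarm-style summary.
    """
    if not attributions:
        raise ConfigurationError("need at least one attribution")
    names = attributions[0].feature_names
    for a in attributions:
        if a.feature_names != names:
            raise ConfigurationError("attributions disagree on feature names")
    phis = np.stack([a.phi for a in attributions])
    values = np.stack([a.instance for a in attributions])
    out = pd.DataFrame(
        {
            "feature": names,
            "mean_abs_phi": np.mean(np.abs(phis), axis=0),
            "mean_phi": phis.mean(axis=0),
            "values": [values[:, j].tolist() for j in range(len(names))],
            "phis": [phis[:, j].tolist() for j in range(len(names))],
        }
    )
    out = out.sort_values("mean_abs_phi", ascending=False, kind="stable")
    out["importance_rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def dependence_interaction(
    attributions: list[AttributionResult],
    feature_x: str,
    feature_color: str,
) -> pd.DataFrame:
    """Plot-ready dependence data: (x value, phi_x, colour value) per instance.

    The zero line ``phi_x = 0`` is the threshold at which the feature flips
    from suppressing to raising the forecast; it is included as a column for
    renderers.
    """
    if not attributions:
        raise ConfigurationError("need at least one attribution")
    names = attributions[0].feature_names
    for name in (feature_x, feature_color):
        if name not in names:
            raise ConfigurationError(f"unknown feature name {name!r}")
    ix, ic = names.index(feature_x), names.index(feature_color)
    rows = [
        {
            "instance_date": a.instance_date,
            "x_value": a.instance[ix],
            "phi_x": a.phi[ix],
            "color_value": a.instance[ic],
        }
        for a in attributions
    ]
    out = pd.DataFrame(rows)
    out["zero_line"] = 0.0
    return out
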