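"""Construction of the default and reduced forecaster banks.

The default bank holds the study's 15 named methods.  Two slots are backed by
substitutes chosen at build time: the gradient-boosted "CatBoost" slot runs on
LightGBM's boosted trees, and the "Prophet" slot runs on the internal additive
structural seasonal model; both substitutions are logged when the bank is
assembled.
"""

from __future__ import annotations

import logging
from typing import Sequence

from ._exceptions import ConfigurationError
from .ensembles import (
    AveragingForecaster,
    EnsembleSpec,
    StackingForecaster,
    VotingForecaster,
)
from .forecasters import (
    ArimaAuto,
    EnhancedPersistence,
    Forecaster,
    InHouseBenchmark,
    Persistence,
    RegressionForecaster,
    SeasonalStructural,
)

logger = logging.getLogger(__name__)

__all__ = ["default_bank", "reduced_bank", "bank_names", "validate_bank"]


def default_bank(seed: int = 0, holidays=None) -> list[Forecaster]:
    """The full 15-method bank, ensembles last so their bases precede them."""
    logger.info(
        "bank: 'CatBoost' slot backed by LightGBM boosted trees; "
        "'Prophet' slot backed by the internal additive structural model"
    )
    bases: list[Forecaster] = [
        InHouseBenchmark(seed=seed),
        Persistence(seed=seed),
        EnhancedPersistence(seed=seed),
        ArimaAuto(seed=seed),
        RegressionForecaster("knn", name="kNN", seed=seed),
        RegressionForecaster("nu_svr", name="SVR (NU)", seed=seed),
        RegressionForecaster("ridge", name="Ridge", seed=seed),
        RegressionForecaster("kernel_ridge", name="Kernel Ridge", seed=seed),
        RegressionForecaster("random_forest", name="Random Forest", seed=seed),
        RegressionForecaster("gradient_boosting", name="Gradient Boosting", seed=seed),
        RegressionForecaster("lightgbm", name="CatBoost", seed=seed),
        SeasonalStructural(holidays=holidays, seed=seed),
    ]
    by_name = {b.name: b for b in bases}
    voting = VotingForecaster(
        EnsembleSpec("voting", ["Prophet", "CatBoost", "Random Forest", "ARIMA"]), seed=seed
    )
    stacking = StackingForecaster(
        EnsembleSpec("stacking", ["Prophet", "CatBoost", "Random Forest"]),
        bases=[by_name[n] for n in ("Prophet", "CatBoost", "Random Forest")],
        seed=seed,
    )
    averaging = AveragingForecaster(
        EnsembleSpec(
            "averaging", ["Prophet", "CatBoost", "Random Forest", "Voting", "Stacking"]
        ),
        seed=seed,
    )
    return bases + [voting, stacking, averaging]


def reduced_bank(seed: int = 0) -> list[Forecaster]:
    """Small bank for scaled-down drift studies: benchmarks, ridge, forest, voting.

    The forest runs 60 trees: at the reduced bank's weekly-refit cadence the
    accuracy difference to a larger forest is negligible while the refits stay
    cheap.
    """
    bank: list[Forecaster] = [
        InHouseBenchmark(seed=seed),
        Persistence(seed=seed),
        EnhancedPersistence(seed=seed),
        RegressionForecaster("ridge", name="Ridge", seed=seed),
        RegressionForecaster(
            "random_forest", name="Random Forest",
            hyperparameters={"n_estimators": 60}, seed=seed,
        ),
        VotingForecaster(
            EnsembleSpec("voting", ["Ridge", "Random Forest", "Naive (Enhanced)"]), seed=seed
        ),
    ]
    return bank


def bank_names(bank: Sequence[Forecaster]) -> list[str]:
    return [m.name for m in bank]


def validate_bank(bank: Sequence[Forecaster]) -> None:
    """Names must be unique and every ensemble base must precede its ensemble."""
    seen: set[str] = set()
    for member in bank:
        if member.name in seen:
            raise ConfigurationError(f"duplicate forecaster name {member.name!r} in bank")
        if member.requires == "ensemble":
            missing = [b for b in member.base_names if b not in seen]
            if missing:
                raise ConfigurationError(
                    f"{member.name}: bases {missing} must appear earlier in the bank"
                )
        seen.add(member.name)
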