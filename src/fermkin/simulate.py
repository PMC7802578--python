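"""Synthetic fermentation time courses.

Emulates the statistical design of the WU14 batch fermentation: observables
sampled every 2 hr over 0-24 hr, with trajectories drawn from the fitted
kinetic-model mean curves plus additive i.i.d. Gaussian noise. Noise is
untruncated — negative noisy readings are kept, because truncating them
would bias downstream parameter-recovery studies.

Seeding rule: one integer seed expands to per-series child seeds through
``numpy.random.SeedSequence(seed).spawn(...)`` in a fixed series order
(biomass, substrate, enzyme activity), so appending a new series never
perturbs the existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import models
from .errors import ConfigError
from .models import (
    BoltzmannParams,
    LogisticGrowthParams,
    LuedekingPiretParams,
    ModelFamily,
    PowerLogisticParams,
)
from .timecourse import PAPER_GRID, Observable, TimeCourse

__all__ = [
    "SyntheticConfig",
    "model_mean",
    "simulate_timecourse",
    "paper_like_configs",
    "paper_like_dataset",
    "DEFAULT_NOISE_FRACTION",
]

DEFAULT_NOISE_FRACTION = 0.02
"""Default residual noise, as a fraction of series amplitude. The true
residual level of the WU14 data is not published; 2% of amplitude is this
package's choice of a realistic bench-scale assay noise."""

_EVAL = {
    ModelFamily.BOLTZMANN: models.boltzmann_eval,
    ModelFamily.POWER_LOGISTIC: models.power_logistic_eval,
    ModelFamily.LOGISTIC_GROWTH: models.logistic_growth_eval,
    ModelFamily.LUEDEKING_PIRET: models.luedeking_piret_eval,
}

_PARAM_TYPE = {
    ModelFamily.BOLTZMANN: BoltzmannParams,
    ModelFamily.POWER_LOGISTIC: PowerLogisticParams,
    ModelFamily.LOGISTIC_GROWTH: LogisticGrowthParams,
    ModelFamily.LUEDEKING_PIRET: LuedekingPiretParams,
}


def model_mean(family: ModelFamily, params, t):
    """Noise-free mean trajectory of ``family`` at time(s) ``t``."""
    family = ModelFamily(family)
    expected = _PARAM_TYPE[family]
    if not isinstance(params, expected):
        raise ConfigError(
            f"family {family.value} requires {expected.__name__}, got {type(params).__name__}"
        )
    return _EVAL[family](params, t)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for one simulated time course.

    The default grid is the experimental design: t = 0, 2, ..., 24 hr.
    """

    family: ModelFamily
    params: object
    observable: Observable
    t_start: float = 0.0
    t_end: float = 24.0
    step: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ModelFamily(self.family))
        object.__setattr__(self, "observable", Observable(self.observable))
        if not self.t_end > self.t_start:
            raise ConfigError("SyntheticConfig: t_end must exceed t_start")
        if self.step <= 0:
            raise ConfigError("SyntheticConfig: step must be positive")
        if self.noise_sd < 0:
            raise ConfigError("SyntheticConfig: noise_sd must be non-negative")
        expected = _PARAM_TYPE[self.family]
        if not isinstance(self.params, expected):
            raise ConfigError(
                f"SyntheticConfig: family {self.family.value} requires "
                f"{expected.__name__}, got {type(self.params).__name__}"
            )

    @property
    def grid(self) -> np.ndarray:
        n = int(np.floor((self.t_end - self.t_start) / self.step + 1e-9)) + 1
        return self.t_start + self.step * np.arange(n)


def simulate_timecourse(config: SyntheticConfig) -> TimeCourse:
    """Draw one time course: model mean + i.i.d. Gaussian noise.

    Deterministic for a fixed config (including seed); with
    ``noise_sd = 0`` the mean trajectory is returned exactly.
    """
    t = config.grid
    mean = np.asarray(model_mean(config.family, config.params, t), dtype=float)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        values = mean + config.noise_sd * rng.standard_normal(len(t))
    else:
        values = mean
    return TimeCourse(times=t, values=values, observable=config.observable)


def _amplitude(family: ModelFamily, params, grid: np.ndarray) -> float:
    mean = np.asarray(model_mean(family, params, grid))
    return float(mean.max() - mean.min())


def paper_like_configs(
    seed: int,
    noise_sd_fractions: Mapping[Observable, float] | float | None = None,
) -> dict[Observable, SyntheticConfig]:
    """Per-observable simulation configs for the coherent WU14 dataset.

    Expands ``seed`` into one child seed per series (fixed order: biomass,
    substrate, enzyme activity) and converts each noise fraction into an
    absolute sd via the series amplitude on the default grid.
    """
    if noise_sd_fractions is None:
        fractions: dict[Observable, float] = {}
    elif isinstance(noise_sd_fractions, Mapping):
        fractions = {Observable(k): float(v) for k, v in noise_sd_fractions.items()}
    else:
        f = float(noise_sd_fractions)
        fractions = {
            Observable.BIOMASS_OD600: f,
            Observable.REDUCING_SUGAR_MG_PER_ML: f,
            Observable.ENZYME_ACTIVITY_U_PER_ML: f,
        }
    series = [
        (Observable.BIOMASS_OD600, ModelFamily.BOLTZMANN, models.WU14_GROWTH_BOLTZMANN),
        (
            Observable.REDUCING_SUGAR_MG_PER_ML,
            ModelFamily.POWER_LOGISTIC,
            models.WU14_SUBSTRATE_POWER_LOGISTIC,
        ),
        (
            Observable.ENZYME_ACTIVITY_U_PER_ML,
            ModelFamily.LUEDEKING_PIRET,
            models.WU14_LAI_LUEDEKING_PIRET,
        ),
    ]
    children = np.random.SeedSequence(seed).spawn(len(series))
    configs: dict[Observable, SyntheticConfig] = {}
    for (obs, family, params), child in zip(series, children):
        frac = fractions.get(obs, DEFAULT_NOISE_FRACTION)
        if frac < 0:
            raise ConfigError("noise fraction must be non-negative")
        configs[obs] = SyntheticConfig(
            family=family,
            params=params,
            observable=obs,
            noise_sd=frac * _amplitude(family, params, PAPER_GRID),
            seed=int(child.generate_state(1)[0]),
        )
    return configs


def paper_like_dataset(
    seed: int,
    noise_sd_fractions: Mapping[Observable, float] | float | None = None,
) -> dict[Observable, TimeCourse]:
    """Simulate the three coherent WU14 observables on the 0-24 hr grid.

    Biomass follows the Boltzmann growth fit, reducing sugar the
    power-logistic substrate fit, and enzyme activity the Luedeking-Piret
    fit whose growth parameters are the shared logistic-growth record. The
    pH series is not simulated (no kinetic model exists for it). Noise sd
    for each series is ``fraction x series amplitude``; fractions default
    to 2% for every observable.
    """
    return {
        obs: simulate_timecourse(cfg)
        for obs, cfg in paper_like_configs(seed, noise_sd_fractions).items()
    }
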