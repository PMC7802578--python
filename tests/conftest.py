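import numpy as np
import pytest

from fermkin import (
    ModelFamily,
    Observable,
    SyntheticConfig,
    simulate_timecourse,
)

_OBSERVABLE_FOR = {
    ModelFamily.BOLTZMANN: Observable.BIOMASS_OD600,
    ModelFamily.POWER_LOGISTIC: Observable.REDUCING_SUGAR_MG_PER_ML,
    ModelFamily.LOGISTIC_GROWTH: Observable.BIOMASS_OD600,
    ModelFamily.LUEDEKING_PIRET: Observable.ENZYME_ACTIVITY_U_PER_ML,
}


@pytest.fixture
def make_timecourse():
    """Factory for simulated series on the 0-24 hr, 2-hr grid."""

    def _make(family, params, noise_sd=0.0, seed=0, observable=None):
        cfg = SyntheticConfig(
            family=family,
            params=params,
            observable=observable or _OBSERVABLE_FOR[ModelFamily(family)],
            noise_sd=noise_sd,
            seed=seed,
        )
        return simulate_timecourse(cfg)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
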