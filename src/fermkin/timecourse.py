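"""The TimeCourse container: one fermentation observable sampled over time."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["Observable", "TimeCourse", "PAPER_GRID"]

PAPER_GRID = np.arange(0.0, 24.0 + 1e-9, 2.0)
"""Default sampling grid: every 2 hr over 0-24 hr (13 points), the design
of the WU14 batch-fermentation experiment."""


class Observable(str, enum.Enum):
    """Kinds of fermentation observable tracked during a batch run."""

    BIOMASS_OD600 = "biomass_od600"
    REDUCING_SUGAR_MG_PER_ML = "reducing_sugar_mg_per_ml"
    ENZYME_ACTIVITY_U_PER_ML = "enzyme_activity_u_per_ml"
    PH = "ph"


_DEFAULT_UNITS = {
    Observable.BIOMASS_OD600: "OD600",
    Observable.REDUCING_SUGAR_MG_PER_ML: "mg/ml",
    Observable.ENZYME_ACTIVITY_U_PER_ML: "U/ml",
    Observable.PH: "pH",
}


@dataclass(frozen=True)
class TimeCourse:
    """One observable sampled over time.

    times  : strictly increasing sampling times (hr)
    values : readings, same length as times, all finite
    observable : the kind of measurement
    units  : free-text unit label (defaults from the observable kind)
    """

    times: np.ndarray
    values: np.ndarray
    observable: Observable
    units: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "observable", Observable(self.observable))
        if times.ndim != 1 or values.ndim != 1:
            raise DomainError("TimeCourse: times and values must be 1-D")
        if len(times) != len(values):
            raise DomainError(
                f"TimeCourse: length mismatch ({len(times)} times, {len(values)} values)"
            )
        if len(times) < 2:
            raise DomainError("TimeCourse: need at least 2 samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise DomainError("TimeCourse: times and values must be finite")
        if not np.all(np.diff(times) > 0):
            raise DomainError("TimeCourse: times must be strictly increasing")
        if not self.units:
            object.__setattr__(self, "units", _DEFAULT_UNITS[self.observable])

    def __len__(self) -> int:
        return len(self.times)
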