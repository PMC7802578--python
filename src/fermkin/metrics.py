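"""Standard-curve calibration and bioprocess rate/yield arithmetic.

Covers the three colorimetric standard curves used to quantify the WU14
fermentation (cysteine-carbazole for d-tagatose, DNS for reducing sugar,
Coomassie G-250 for protein) plus the before/after percentage metrics of
the downstream purification train (decolorization, protein removal, sugar
recovery) and the substrate-to-product conversion arithmetic.

A standard curve is the affine model ``absorbance = slope * concentration
+ intercept``; inverse prediction divides the blank-corrected absorbance
by the slope. Readings below the blank produce a *negative* concentration
which is returned as-is with a warning rather than clamped — clamping
would silently hide blank-subtraction problems and break invertibility.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError

__all__ = [
    "Analyte",
    "CalibrationCurve",
    "ProcessStep",
    "ProcessStepRecord",
    "concentration_from_absorbance",
    "absorbance_from_concentration",
    "fit_calibration",
    "read_calibration_table",
    "percent_change_rate",
    "recovery_rate",
    "conversion_rate",
    "convert_volumetric_rate",
    "chain_recovery",
    "molar_to_g_per_l",
    "GALACTOSE_MOLAR_MASS_G_PER_MOL",
    "WU14_TAGATOSE_CURVE",
    "WU14_REDUCING_SUGAR_CURVE",
    "WU14_PROTEIN_CURVE",
]

GALACTOSE_MOLAR_MASS_G_PER_MOL = 180.16


class Analyte(str, enum.Enum):
    D_TAGATOSE = "d_tagatose"
    REDUCING_SUGAR = "reducing_sugar"
    PROTEIN = "protein"


class ProcessStep(str, enum.Enum):
    DECOLORIZATION = "decolorization"
    DEPROTEINIZATION = "deproteinization"
    DESALTING = "desalting"
    CHROMATOGRAPHY = "chromatography"


class BelowBlankWarning(UserWarning):
    """Absorbance below the calibration intercept gave a negative concentration."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve: absorbance = slope * concentration + intercept."""

    analyte: Analyte
    slope: float
    intercept: float
    r_squared: float
    conc_units: str

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise DomainError("CalibrationCurve: slope must be nonzero")
        if self.r_squared > 1:
            raise DomainError("CalibrationCurve: r_squared cannot exceed 1")


@dataclass(frozen=True)
class ProcessStepRecord:
    """One purification step with its before/after measure and percent rate."""

    step: ProcessStep
    input_amount: float
    output_amount: float
    rate_percent: float

    def __post_init__(self) -> None:
        if self.input_amount < 0 or self.output_amount < 0:
            raise DomainError("ProcessStepRecord: amounts must be non-negative")


# Published standard curves for the WU14 workflow (absorbance vs
# concentration, ordinary least squares)
WU14_TAGATOSE_CURVE = CalibrationCurve(
    Analyte.D_TAGATOSE, slope=0.0239, intercept=0.0244, r_squared=0.9987, conc_units="mg/ml"
)
WU14_REDUCING_SUGAR_CURVE = CalibrationCurve(
    Analyte.REDUCING_SUGAR, slope=1.1719, intercept=-0.0194, r_squared=0.9964, conc_units="mg/ml"
)
WU14_PROTEIN_CURVE = CalibrationCurve(
    Analyte.PROTEIN, slope=8.0597, intercept=0.0502, r_squared=0.9856, conc_units="mg/ml"
)


def concentration_from_absorbance(curve: CalibrationCurve, absorbance: float) -> float:
    """Inverse-predict concentration: (absorbance - intercept)/slope.

    A result below zero (reading under the blank) is returned unchanged
    with a :class:`BelowBlankWarning`.
    """
    conc = (absorbance - curve.intercept) / curve.slope
    if np.any(np.asarray(conc) < 0):
        warnings.warn(
            f"absorbance {absorbance!r} is below the blank of the "
            f"{curve.analyte.value} curve; negative concentration returned",
            BelowBlankWarning,
            stacklevel=2,
        )
    return conc


def absorbance_from_concentration(curve: CalibrationCurve, concentration: float) -> float:
    """Forward-predict absorbance: slope * concentration + intercept."""
    return curve.slope * concentration + curve.intercept


def fit_calibration(
    concentrations,
    absorbances,
    analyte: Analyte,
    conc_units: str = "mg/ml",
) -> CalibrationCurve:
    """Ordinary least-squares standard curve from paired standards."""
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.shape != absb.shape or conc.ndim != 1 or len(conc) < 2:
        raise DomainError("fit_calibration needs two equal-length 1-D arrays of >= 2 points")
    if np.ptp(conc) == 0:
        raise DomainError("fit_calibration: concentrations are all identical")
    slope, intercept = np.polyfit(conc, absb, 1)
    pred = slope * conc + intercept
    ss_tot = float(np.sum((absb - absb.mean()) ** 2))
    r2 = 1.0 - float(np.sum((absb - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(analyte, float(slope), float(intercept), r2, conc_units)


def read_calibration_table(path, analyte: Analyte, conc_units: str = "mg/ml") -> CalibrationCurve:
    """Fit a standard curve from a delimited text table.

    Expects a header with ``concentration`` and ``absorbance`` columns
    (comma- or tab-separated).
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read calibration table {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "concentration" not in cols or "absorbance" not in cols:
        raise ParseError(
            f"calibration table {path} must have 'concentration' and 'absorbance' columns"
        )
    return fit_calibration(df[cols["concentration"]], df[cols["absorbance"]], analyte, conc_units)


def percent_change_rate(before: float, after: float) -> float:
    """Percent removed/changed between a before and after measure.

    Used for decolorization and protein-removal rates:
    (before - after)/before * 100. ``after > before`` yields a negative
    rate, returned with a warning.
    """
    if before <= 0:
        raise DomainError("percent_change_rate requires before > 0")
    if after < 0:
        raise DomainError("percent_change_rate requires after >= 0")
    rate = (before - after) / before * 100.0
    if after > before:
        warnings.warn("after exceeds before; negative change rate returned", UserWarning, stacklevel=2)
    return rate


def recovery_rate(amount_out: float, amount_in: float) -> float:
    """Percent of material surviving a step: out/in * 100."""
    if amount_in <= 0:
        raise DomainError("recovery_rate requires amount_in > 0")
    return amount_out / amount_in * 100.0


def chain_recovery(step_percents) -> float:
    """Overall recovery of chained steps: product of step recoveries."""
    total = 100.0
    for p in step_percents:
        total *= p / 100.0
    return total


def conversion_rate(product_conc_g_per_l: float, substrate_initial_conc_g_per_l: float) -> float:
    """Substrate-to-product conversion: product/substrate * 100 (mass basis)."""
    if substrate_initial_conc_g_per_l <= 0:
        raise DomainError("conversion_rate requires a positive initial substrate concentration")
    return product_conc_g_per_l / substrate_initial_conc_g_per_l * 100.0


def molar_to_g_per_l(molarity: float, molar_mass_g_per_mol: float) -> float:
    """Convert a molar concentration to g/L."""
    return molarity * molar_mass_g_per_mol


def convert_volumetric_rate(rate_mg_per_ml_hr: float) -> float:
    """Convert a volumetric productivity from mg/(ml*hr) to g/(L*day).

    mg/ml and g/L are the same concentration, so the factor is exactly 24.
    (The WU14 report prints 2.5338 mg/(ml*hr) alongside 49.68 g/(L*d),
    which disagree by a factor of ~1.22; this converter applies the exact
    unit algebra and reproduces neither printed pairing.)
    """
    if rate_mg_per_ml_hr < 0:
        raise DomainError("volumetric rate must be non-negative")
    return rate_mg_per_ml_hr * 24.0
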