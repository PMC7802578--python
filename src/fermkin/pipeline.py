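"""End-to-end fitting workflow: read series, fit families, write reports.

Mirrors the batch-fermentation modelling workflow: the biomass series is
fitted with the Boltzmann and logistic-growth families, the reducing-sugar
series with the power-logistic and Boltzmann families, and the
enzyme-activity series with the Boltzmann and Luedeking-Piret families —
the Luedeking-Piret candidate inheriting the logistic-growth parameters
estimated from the biomass series.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__ as _version
from .errors import ConfigError, SelectionError
from .fitting import (
    FitResult,
    ModelSelection,
    fit_model,
    select_model,
)
from .io import read_timecourse, write_sidecar, write_timecourse
from .models import LogisticGrowthParams, ModelFamily
from .simulate import DEFAULT_NOISE_FRACTION
from .timecourse import Observable, TimeCourse

__all__ = ["RunConfig", "FitReport", "run_fit", "run_simulate", "DEFAULT_FAMILIES"]

DEFAULT_FAMILIES: dict[Observable, tuple[ModelFamily, ...]] = {
    Observable.BIOMASS_OD600: (ModelFamily.BOLTZMANN, ModelFamily.LOGISTIC_GROWTH),
    Observable.REDUCING_SUGAR_MG_PER_ML: (ModelFamily.POWER_LOGISTIC, ModelFamily.BOLTZMANN),
    Observable.ENZYME_ACTIVITY_U_PER_ML: (ModelFamily.BOLTZMANN, ModelFamily.LUEDEKING_PIRET),
}

_SIM_FILES = {
    Observable.BIOMASS_OD600: "biomass_od600",
    Observable.REDUCING_SUGAR_MG_PER_ML: "reducing_sugar",
    Observable.ENZYME_ACTIVITY_U_PER_ML: "enzyme_activity",
}


@dataclass(frozen=True)
class RunConfig:
    """One fitting run: input file per observable, families, criterion."""

    inputs: Mapping[Observable, Path]
    families: Mapping[Observable, Sequence[ModelFamily]] = field(default_factory=dict)
    criterion: str = "r_squared"
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ConfigError("RunConfig: no input series given")
        inputs = {Observable(k): Path(v) for k, v in self.inputs.items()}
        object.__setattr__(self, "inputs", inputs)
        fams: dict[Observable, tuple[ModelFamily, ...]] = {}
        for obs in inputs:
            requested = self.families.get(obs) if self.families else None
            if requested is None:
                requested = DEFAULT_FAMILIES.get(obs)
            if not requested:
                raise ConfigError(f"RunConfig: no model families for observable {obs.value}")
            fams[obs] = tuple(ModelFamily(f) for f in requested)
        object.__setattr__(self, "families", fams)
        if self.criterion not in ("r_squared", "aicc"):
            raise ConfigError(f"RunConfig: unknown criterion {self.criterion!r}")
        for obs, p in inputs.items():
            if not p.exists():
                raise ConfigError(f"RunConfig: input for {obs.value} does not exist: {p}")


@dataclass(frozen=True)
class FitReport:
    """Per-observable model selections plus provenance."""

    selections: Mapping[Observable, ModelSelection]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "selections": {obs.value: sel.to_dict() for obs, sel in self.selections.items()},
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = []
        for obs, sel in self.selections.items():
            best = sel.best
            lines.append(f"{obs.value}:")
            lines.append(f"  chosen model : {best.family.value}  (criterion: {sel.criterion})")
            lines.append(f"  equation     : {best.equation}")
            lines.append(f"  R^2          : {best.r_squared:.5f}")
            for cand in sel.candidates:
                mark = "*" if cand is best else " "
                lines.append(
                    f"   {mark} {cand.family.value:16s} R^2 = {cand.r_squared:.5f}"
                    f"  converged = {cand.converged}"
                )
        return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _growth_from_biomass(tc: TimeCourse) -> LogisticGrowthParams:
    fit = fit_model(tc, ModelFamily.LOGISTIC_GROWTH)
    if not fit.converged:
        raise SelectionError("logistic-growth fit of the biomass series did not converge")
    return fit.params


def run_fit(config: RunConfig) -> FitReport:
    """Fit every configured observable and assemble the report.

    If any requested family is Luedeking-Piret, a biomass series must be
    present: its logistic-growth fit supplies the shared growth
    parameters.
    """
    series = {obs: read_timecourse(path, obs) for obs, path in config.inputs.items()}
    needs_growth = any(
        ModelFamily.LUEDEKING_PIRET in fams for fams in config.families.values()
    )
    growth = None
    if needs_growth:
        biomass = series.get(Observable.BIOMASS_OD600)
        if biomass is None:
            raise ConfigError(
                "Luedeking-Piret fitting requires a biomass series to estimate growth"
            )
        growth = _growth_from_biomass(biomass)

    selections: dict[Observable, ModelSelection] = {}
    for obs, tc in series.items():
        fams = config.families[obs]
        if len(fams) == 1:
            fit = fit_model(tc, fams[0], growth=growth)
            if not fit.converged:
                raise SelectionError(f"{fams[0].value} fit of {obs.value} did not converge")
            selections[obs] = ModelSelection(
                candidates=(fit,), chosen=0, criterion=config.criterion
            )
        else:
            selections[obs] = select_model(tc, fams, config.criterion, growth=growth)

    provenance = {
        "package": "fermkin",
        "version": _version,
        "criterion": config.criterion,
        "inputs": {
            obs.value: {"path": str(path), "sha256": _sha256(path)}
            for obs, path in config.inputs.items()
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    report = FitReport(selections=selections, provenance=provenance)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "fit_report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        (outdir / "fit_report.txt").write_text(report.summary() + "\n", encoding="utf-8")
    return report


def run_simulate(
    output_dir,
    seed: int,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    force: bool = False,
) -> dict[Observable, Path]:
    """Write the three simulated WU14 series plus JSON sidecars.

    Refuses to overwrite existing series files unless ``force`` is set.
    """
    from .simulate import paper_like_configs, simulate_timecourse

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets = {obs: outdir / f"{stem}.csv" for obs, stem in _SIM_FILES.items()}
    existing = [p for p in targets.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite {existing[0]} (and possibly others); use force"
        )
    written: dict[Observable, Path] = {}
    for obs, cfg in paper_like_configs(seed, noise_fraction).items():
        path = targets[obs]
        write_timecourse(simulate_timecourse(cfg), path)
        write_sidecar(cfg, path.with_suffix(".json"))
        written[obs] = path
    return written
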