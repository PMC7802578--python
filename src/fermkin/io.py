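"""Delimited-text time-course I/O.

The on-disk format is UTF-8 text with the header ``time_hr,value`` and one
``time,value`` pair per line, decimal point ".". Parse failures name the
offending 1-based line. Simulated series carry a JSON sidecar recording
the generating configuration for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import DomainError, ParseError
from .fitting import params_to_dict
from .simulate import SyntheticConfig
from .timecourse import Observable, TimeCourse

__all__ = ["read_timecourse", "write_timecourse", "write_sidecar", "read_sidecar"]

HEADER = "time_hr,value"
SIDECAR_SCHEMA = "fermkin.simulation.v1"


def read_timecourse(path, observable: Observable) -> TimeCourse:
    """Parse a ``time_hr,value`` file into a validated TimeCourse."""
    path = Path(path)
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not lines:
        raise ParseError(f"{path}: empty file", line=1)
    if [c.strip() for c in lines[0].split(",")] != ["time_hr", "value"]:
        raise ParseError(f"{path}: expected header '{HEADER}', got {lines[0]!r}", line=1)
    times: list[float] = []
    values: list[float] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split(",")
        if len(cells) != 2:
            raise ParseError(f"{path}: expected 2 comma-separated cells, got {len(cells)}", line=lineno)
        try:
            t, v = float(cells[0]), float(cells[1])
        except ValueError:
            raise ParseError(f"{path}: non-numeric cell in {raw!r}", line=lineno) from None
        if times and t <= times[-1]:
            raise ParseError(
                f"{path}: time {t} does not increase past previous {times[-1]}", line=lineno
            )
        times.append(t)
        values.append(v)
    try:
        return TimeCourse(np.array(times), np.array(values), observable)
    except DomainError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timecourse(tc: TimeCourse, path) -> None:
    path = Path(path)
    rows = "\n".join(f"{t:g},{v:.10g}" for t, v in zip(tc.times, tc.values))
    path.write_text(f"{HEADER}\n{rows}\n", encoding="utf-8")


def write_sidecar(config: SyntheticConfig, path) -> None:
    """Record the full generating configuration next to a simulated series."""
    doc = {
        "schema": SIDECAR_SCHEMA,
        "family": config.family.value,
        "params": params_to_dict(config.params),
        "observable": config.observable.value,
        "t_start": config.t_start,
        "t_end": config.t_end,
        "step": config.step,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_sidecar(path) -> dict:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != SIDECAR_SCHEMA:
        raise ParseError(f"{path}: not a {SIDECAR_SCHEMA} document")
    return doc
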