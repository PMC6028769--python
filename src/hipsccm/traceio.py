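"""Trace readers/writers and run-configuration validation.

Traces are stored as CSV with a one-line ``# units:`` header comment and a
sidecar ``<name>.meta.json`` capturing protocol, parameter set, solver
settings and package version — enough provenance to re-execute the run.
Columns are name-keyed, so column order is irrelevant on read; external
recordings (e.g. fluorescence time series in arbitrary units) are accepted
as long as a time column is present.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import model
from .simulate import Protocol, Trace

__all__ = ["write_trace", "read_trace", "RunConfig", "load_run_config"]

_UNITS = {"t": "s", "Vm": "V", "Ca_SR": "mM", "Ca_i": "mM", "Na_i": "mM"}


def write_trace(path: str | Path, trace: Trace, *,
                include_currents: bool = False) -> Path:
    """Write a trace as CSV (+ ``.meta.json`` sidecar); returns the path."""
    path = Path(path)
    df = trace.to_frame(include_currents=include_currents)
    units = [_UNITS.get(c, "-") for c in df.columns]
    with open(path, "w") as fh:
        fh.write("# units: " + ",".join(units) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    meta = {
        "package_version": _pkg_version,
        "parameter_set": trace.params.name if trace.params else None,
        "protocol": asdict(trace.protocol) if trace.protocol else None,
        "solver": trace.solver,
        "final_state": (None if trace.final_state is None
                        else [float(v) for v in trace.final_state]),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path, params=None) -> Trace:
    """Read a trace CSV written by :func:`write_trace` (or any tabular
    time-series with a ``t`` column).

    Missing state columns are filled with NaN so partial recordings (e.g. a
    bare membrane-potential or fluorescence trace) can still feed the
    biomarker extractors.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        skip = 1 if first.startswith("#") else 0
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as exc:
        raise ValueError(f"{path}: malformed trace file (line 1): {exc}")
    if "t" not in df.columns:
        raise ValueError(
            f"{path}: missing required time column 't' "
            f"(line {skip + 1}: header {list(df.columns)!r})")
    n = len(df)
    states = np.full((n, model.NSTATES), np.nan)
    for i, name in enumerate(model.STATE_NAMES):
        if name in df.columns:
            states[:, i] = df[name].to_numpy(float)
    protocol = None
    solver: dict = {}
    final_state = None
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("protocol"):
            protocol = Protocol(**meta["protocol"])
        solver = meta.get("solver", {})
        if meta.get("final_state"):
            final_state = np.array(meta["final_state"])
    return Trace(t=df["t"].to_numpy(float), states=states, params=params,
                 protocol=protocol, solver=solver, final_state=final_state)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a CLI run."""

    params: str = "paci2018-optimized"
    mode: str = "spontaneous"
    pacing_rate: float = 1.0
    stim_amplitude_pA: float = 550.0
    stim_duration: float = 0.005
    pre_run_duration: float = 800.0
    duration: float = 20.0
    rtol: float = 1e-7
    atol: float = 1e-9
    dt_out: float = 1e-4
    out: str = "."
    log_level: str = "INFO"
    environment: dict = field(default_factory=dict)
    block: dict = field(default_factory=dict)

    def protocol(self) -> Protocol:
        return Protocol(mode=self.mode, pacing_rate=self.pacing_rate,
                        stim_amplitude_pA=self.stim_amplitude_pA,
                        stim_duration=self.stim_duration,
                        pre_run_duration=self.pre_run_duration)


def load_run_config(source: str | Path | dict) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file or dict; unknown keys
    are rejected with the offending name."""
    import yaml

    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text()) or {}
    else:
        doc = dict(source)
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; valid keys: "
            f"{sorted(valid)}")
    return RunConfig(**doc)
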