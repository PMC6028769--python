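"""Stiff-ODE simulation engine and stimulation/environment protocols.

Simulations use :func:`scipy.integrate.solve_ivp` with a stiff method
(LSODA by default; BDF available).  Pacing is implemented by splitting the
integration at every stimulus edge so the solver never steps across a
discontinuity of the forcing; within a segment the stimulus current is
constant and lives in the packed parameter vector.

Long pre-runs (hundreds of seconds, used to reach the limit cycle) store no
trajectory; analysis windows are sampled on a uniform grid (0.1 ms default)
fine enough for upstroke-velocity biomarkers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from . import model
from .parameters import ModelParameters, apply_block, make_immature_ryr  # noqa: F401

__all__ = [
    "Protocol", "Trace", "SimulationError", "BlockResult",
    "simulate", "prerun", "packaged_steady_state",
    "run_block_experiment", "run_hypercalcemia_dad", "run_environment_series",
]

DEFAULT_RTOL = 1e-7
DEFAULT_ATOL = 1e-9
DEFAULT_DT_OUT = 1e-4  # s


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid time and state."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(f"{message} (t={t:.6g} s)")
        self.t = t
        self.state = state


@dataclass(frozen=True)
class Protocol:
    """Stimulation and environment description.

    ``mode`` is ``"spontaneous"`` (no stimulus) or ``"paced"``.  The stimulus
    is a rectangular pulse of ``stim_amplitude_pA`` picoamperes lasting
    ``stim_duration`` seconds, delivered at ``pacing_rate`` Hz.
    """

    mode: str = "spontaneous"
    pacing_rate: float = 1.0        # Hz, paced mode only
    stim_amplitude_pA: float = 550.0
    stim_duration: float = 0.005    # s
    pre_run_duration: float = 800.0  # s

    def __post_init__(self) -> None:
        if self.mode not in ("spontaneous", "paced"):
            raise ValueError("mode must be 'spontaneous' or 'paced'")
        if self.mode == "paced" and self.pacing_rate <= 0:
            raise ValueError("pacing_rate must be > 0")


SPONTANEOUS = Protocol(mode="spontaneous")


@dataclass
class Trace:
    """Uniformly sampled simulation output.

    ``states`` has one row per time point and one column per state variable
    (ordering :data:`hipsccm.model.STATE_NAMES`).  ``final_state`` is the
    solver's terminal state, suitable for chaining simulations.
    """

    t: np.ndarray
    states: np.ndarray
    params: ModelParameters
    protocol: Protocol | None = None
    solver: dict = field(default_factory=dict)
    final_state: np.ndarray | None = None

    @property
    def Vm(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def Ca_SR(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def Ca_i(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def Na_i(self) -> np.ndarray:
        return self.states[:, 17]

    def currents(self) -> dict[str, np.ndarray]:
        vals = model.compute_currents_trace(self.states, self.params)
        return dict(zip(model.CURRENT_NAMES, vals.T))

    def to_frame(self, include_currents: bool = False):
        import pandas as pd

        data = {"t": self.t}
        data.update({n: self.states[:, i]
                     for i, n in enumerate(model.STATE_NAMES)})
        if include_currents:
            data.update(self.currents())
        return pd.DataFrame(data)


def _segments(protocol: Protocol, t0: float, t1: float,
              stim_density: float) -> list[tuple[float, float, float]]:
    """Stimulus-constant segments covering [t0, t1] as (start, end, stim)."""
    if protocol.mode == "spontaneous":
        return [(t0, t1, 0.0)]
    period = 1.0 / protocol.pacing_rate
    w = protocol.stim_duration
    edges = {t0, t1}
    k0 = int(np.floor(t0 / period))
    k1 = int(np.ceil(t1 / period)) + 1
    for k in range(k0, k1):
        for e in (k * period, k * period + w):
            if t0 < e < t1:
                edges.add(e)
    cuts = sorted(edges)
    segs = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        phase = mid % period
        segs.append((a, b, stim_density if phase < w else 0.0))
    return segs


def _integrate(params: ModelParameters, protocol: Protocol,
               y0: np.ndarray, t0: float, t1: float,
               rtol: float, atol, method: str,
               t_store: np.ndarray | None):
    """Core segmented integration; returns (stored_states, final_state)."""
    pvec = model.pack_parameters(params)
    stim_density = protocol.stim_amplitude_pA * 1e-12 / params.Cm
    stored = ([] if t_store is None
              else np.empty((len(t_store), model.NSTATES)))
    y = np.asarray(y0, dtype=float).copy()
    if t_store is not None and len(t_store) and t_store[0] == t0:
        stored[0] = y
        first = 1
    else:
        first = 0
    idx = first
    core = model.rhs_core

    for a, b, stim in _segments(protocol, t0, t1, stim_density):
        pvec[model.NPARAMS - 1] = stim
        p = pvec.copy()

        if t_store is not None:
            inside = t_store[(t_store > a) & (t_store <= b)]
        else:
            inside = np.empty(0)
        t_eval = np.unique(np.concatenate([inside, [b]]))
        sol = solve_ivp(lambda t, yy: core(t, yy, p), (a, b), y,
                        method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise SimulationError(
                f"stiff solver failed: {sol.message}", sol.t[-1] if len(sol.t)
                else a, sol.y[:, -1] if sol.y.size else y)
        if len(inside):
            n = len(inside)
            # columns of sol.y follow t_eval; the last column is b
            cols = np.searchsorted(sol.t, inside)
            stored[idx:idx + n] = sol.y[:, cols].T
            idx += n
        y = sol.y[:, -1].copy()
    return stored, y


def simulate(params: ModelParameters, protocol: Protocol,
             initial: np.ndarray, duration: float, *,
             t0: float = 0.0,
             rtol: float = DEFAULT_RTOL, atol=DEFAULT_ATOL,
             method: str = "LSODA",
             dt_out: float = DEFAULT_DT_OUT) -> Trace:
    """Integrate the model for ``duration`` seconds and return a Trace.

    The output is sampled on the uniform grid ``t0 + k*dt_out``.  The result
    is deterministic: identical inputs and solver settings give identical
    traces.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = max(int(round(duration / dt_out)), 1)
    t_store = t0 + dt_out * np.arange(n + 1)
    t_store[-1] = t0 + duration
    stored, y_end = _integrate(params, protocol, initial, t0, t0 + duration,
                               rtol, atol, method, t_store)
    return Trace(t=t_store, states=stored, params=params, protocol=protocol,
                 solver={"method": method, "rtol": rtol, "atol": atol,
                         "dt_out": dt_out},
                 final_state=y_end)


def prerun(params: ModelParameters, protocol: Protocol,
           initial: np.ndarray, duration: float, *,
           t0: float = 0.0, rtol: float = DEFAULT_RTOL,
           atol=DEFAULT_ATOL, method: str = "LSODA") -> np.ndarray:
    """Integrate without storing the trajectory; returns the final state."""
    if duration <= 0:
        return np.asarray(initial, dtype=float).copy()
    _, y_end = _integrate(params, protocol, initial, t0, t0 + duration,
                          rtol, atol, method, None)
    return y_end


# -- packaged steady states ---------------------------------------------

def packaged_steady_state(mode: str = "spontaneous") -> np.ndarray:
    """Stored steady state of the optimized model (800 s pre-run).

    ``mode``: ``"spontaneous"`` or ``"paced-1hz"``.  Regenerate with
    :func:`regenerate_steady_states` after model changes.
    """
    path = importlib.resources.files("hipsccm") / "data" / "steady_states.yaml"
    doc = yaml.safe_load(path.read_text())
    key = f"paci2018-optimized/{mode}"
    if key not in doc:
        raise KeyError(f"no packaged steady state {key!r}")
    return np.array(doc[key], dtype=float)


def regenerate_steady_states(out_path=None) -> dict:
    """Maintenance command: re-run the 800 s pre-runs and store the states."""
    from .parameters import load_parameters

    params = load_parameters("paci2018-optimized")
    doc = {}
    y = prerun(params, SPONTANEOUS, model.default_initial_state(), 800.0)
    doc["paci2018-optimized/spontaneous"] = [float(v) for v in y]
    paced = Protocol(mode="paced", pacing_rate=1.0, stim_amplitude_pA=550.0)
    y = prerun(params, paced, model.default_initial_state(), 800.0)
    doc["paci2018-optimized/paced-1hz"] = [float(v) for v in y]
    if out_path is None:
        out_path = (importlib.resources.files("hipsccm") / "data"
                    / "steady_states.yaml")
    with open(str(out_path), "w") as fh:
        yaml.safe_dump(doc, fh)
    return doc


# -- protocol-level experiments ------------------------------------------

@dataclass
class BlockResult:
    """Outcome of one current-block arm vs its paced control."""

    control: object            # APBiomarkers
    blocked: object            # APBiomarkers
    changes: dict[str, float]  # blocked/control x 100% per biomarker
    capture_control: bool      # one AP per stimulus in the control arm
    capture_blocked: bool      # one AP per stimulus in the blocked arm


def run_block_experiment(params: ModelParameters, block: dict[str, float],
                         stim_amplitude_pA: float = 550.0, *,
                         stim_duration: float = 0.005,
                         pre_run: float = 800.0, drug_run: float = 400.0,
                         window: float = 20.0,
                         pre_state: np.ndarray | None = None,
                         rtol: float = DEFAULT_RTOL, atol=DEFAULT_ATOL) -> "BlockResult":
    """Paced current-block experiment: control arm vs blocked arm.

    Both arms pace at 1 Hz.  The control arm is pre-run for ``pre_run``
    seconds (skipped if ``pre_state``, a paced steady state, is given); the
    drug arm continues for ``drug_run`` seconds with the block applied, and
    biomarkers are computed on the final ``window`` seconds of each arm.
    Relative changes are reported as blocked/control x 100%.

    If an arm fails to follow the stimulus one-to-one (possible at deep Na+
    block), the result carries an explicit capture flag and biomarkers are
    computed on the elicited APs; an arm with no APs at all raises
    :class:`SimulationError`.
    """
    from . import biomarkers as bm

    protocol = Protocol(mode="paced", pacing_rate=1.0,
                        stim_amplitude_pA=stim_amplitude_pA,
                        stim_duration=stim_duration)
    if pre_state is None:
        pre_state = prerun(params, protocol, model.default_initial_state(),
                           pre_run, rtol=rtol, atol=atol)
    ctrl_trace = simulate(params, protocol, pre_state, window,
                          rtol=rtol, atol=atol)
    control = bm.ap_biomarkers(ctrl_trace)

    blocked_params = apply_block(params, block)
    y = prerun(blocked_params, protocol, pre_state, drug_run,
               rtol=rtol, atol=atol)
    drug_trace = simulate(blocked_params, protocol, y, window,
                          t0=drug_run, rtol=rtol, atol=atol)
    try:
        blocked = bm.ap_biomarkers(drug_trace)
    except bm.InsufficientDataError as exc:
        raise SimulationError(f"no APs elicited in blocked arm: {exc}",
                              drug_run + window, drug_trace.final_state)

    changes = {}
    for name in ("APA", "MDP", "Vmax", "APD10", "APD30", "APD50", "APD90"):
        c = getattr(control, name)
        b = getattr(blocked, name)
        changes[name] = 100.0 * b / c
    expected = int(np.floor(window * protocol.pacing_rate))
    return BlockResult(
        control=control, blocked=blocked, changes=changes,
        capture_control=control.n_detected >= expected - 1,
        capture_blocked=blocked.n_detected >= expected - 1)


def run_hypercalcemia_dad(params: ModelParameters, *,
                          Ca_o: float = 3.945, duration: float = 60.0,
                          pre_state: np.ndarray | None = None,
                          pre_run: float = 800.0,
                          pacing_rate: float | None = None,
                          rtol: float = DEFAULT_RTOL, atol=DEFAULT_ATOL) -> Trace:
    """Ca2+-overload protocol: raise extracellular Ca2+ and record.

    Pre-runs the model spontaneously at the nominal Ca_o (800 s, skipped if
    ``pre_state`` is given), switches Ca_o to ``Ca_o`` mM instantaneously and
    simulates ``duration`` seconds.  ``pacing_rate`` switches the post-switch
    phase to paced mode (used for the elevated-rate variant).
    """
    if pre_state is None:
        pre_state = prerun(params, SPONTANEOUS, model.default_initial_state(),
                           pre_run, rtol=rtol, atol=atol)
    over = params.with_values(Ca_o=Ca_o)
    over = replace(over, name=params.name)
    if pacing_rate is None:
        protocol = SPONTANEOUS
    else:
        protocol = Protocol(mode="paced", pacing_rate=pacing_rate,
                            stim_amplitude_pA=550.0)
    return simulate(over, protocol, pre_state, duration,
                    rtol=rtol, atol=atol)


def run_environment_series(params: ModelParameters,
                           overrides: Sequence[dict[str, float]], *,
                           pre_state: np.ndarray | None = None,
                           pre_run: float = 800.0, settle: float = 300.0,
                           window: float = 100.0,
                           rtol: float = DEFAULT_RTOL, atol=DEFAULT_ATOL):
    """Spontaneous Ca2+-transient rate under ionic-environment changes.

    Each override is a dict of extracellular concentrations (``Na_o``,
    ``K_o``, ``Ca_o`` in mM) applied instantaneously to the spontaneous
    steady state; the rate is measured over the last ``window`` seconds of a
    ``settle + window`` second run.  Returns a list of dicts with keys
    ``override``, ``rate`` (Hz or None when activity stopped) and
    ``change_pct`` vs. the baseline (first computed internally).
    """
    from . import biomarkers as bm

    if pre_state is None:
        pre_state = prerun(params, SPONTANEOUS, model.default_initial_state(),
                           pre_run, rtol=rtol, atol=atol)

    def rate_for(p: ModelParameters) -> float | None:
        y = prerun(p, SPONTANEOUS, pre_state, settle, rtol=rtol, atol=atol)
        trace = simulate(p, SPONTANEOUS, y, window, t0=settle,
                         rtol=rtol, atol=atol, dt_out=1e-3)
        try:
            cat = bm.cat_biomarkers(trace)
        except bm.InsufficientDataError:
            return None
        return cat.FREQ

    baseline = rate_for(params)
    rows = [{"override": {}, "rate": baseline, "change_pct": 0.0}]
    for ov in overrides:
        p = params.with_values(**ov)
        r = rate_for(p)
        change = None if r is None else 100.0 * (r - baseline) / baseline
        rows.append({"override": dict(ov), "rate": r, "change_pct": change})
    return rows
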