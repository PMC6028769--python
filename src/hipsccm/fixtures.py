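"""Synthetic AP-like and Ca2+-transient-like waveforms with known biomarkers.

These generators exist so the biomarker and cost modules can be tested
against closed-form ground truth, independently of the ODE model.  Three
waveform families are provided:

``rectangular``
    Instant rise to baseline+amplitude, flat plateau, instant return.
``triangular``
    Linear rise over ``rise`` seconds, linear decay over ``decay`` seconds.
``piecewise-exponential``
    Linear rise over ``rise`` seconds, exponential decay with time constant
    ``decay`` (suitable for Ca2+-transient-like shapes).

``generate`` returns both the sampled trace and the biomarkers implied by
the geometry (e.g. a linear decay crosses 90% -> 10% of the amplitude in 0.8
of the decay time).  Additive white Gaussian noise is optional and seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WaveformSpec", "FixtureTrace", "generate", "inject_dad"]


@dataclass(frozen=True)
class WaveformSpec:
    """Geometry of a periodic event train.

    Times in seconds; levels in the signal's units (mV for AP-like, mM or
    arbitrary fluorescence units for Ca2+-like signals).
    """

    family: str = "triangular"
    baseline: float = 0.0
    amplitude: float = 1.0
    rise: float = 0.0       # s (ignored by rectangular)
    plateau: float = 0.0    # s (rectangular only)
    decay: float = 0.0      # s (ramp length, or exp time constant)
    period: float = 1.0     # s
    count: int = 5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("rectangular", "triangular",
                               "piecewise-exponential"):
            raise ValueError(f"unknown waveform family {self.family!r}")
        if self.amplitude <= 0 or self.period <= 0 or self.count < 1:
            raise ValueError("amplitude, period and count must be positive")
        width = self.event_width()
        if width >= self.period:
            raise ValueError(
                f"overlapping events: event width {width:.3g} s >= "
                f"period {self.period:.3g} s")

    def event_width(self) -> float:
        if self.family == "rectangular":
            return self.rise + self.plateau
        if self.family == "triangular":
            return self.rise + self.decay
        # exponential decay: practically over after 7 time constants
        return self.rise + 7.0 * self.decay


@dataclass
class FixtureTrace:
    """Sampled synthetic trace; quacks like a simulation Trace.

    The same sample vector is exposed as both ``Vm`` (volts) and ``Ca_i``
    so either biomarker extractor can consume it; ``signal`` holds the raw
    values in the spec's units.  ``ground_truth`` maps biomarker names to
    their closed-form values (ms / mV / Hz conventions), and ``events``
    records injected afterdepolarization ground truth.
    """

    t: np.ndarray
    signal: np.ndarray
    kind: str                 # "ap" or "cat"
    ground_truth: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    @property
    def Vm(self) -> np.ndarray:
        return self.signal * 1e-3  # mV -> V

    @property
    def Ca_i(self) -> np.ndarray:
        return self.signal


def _event_value(spec: WaveformSpec, tau: float) -> float:
    """Waveform value above baseline at time tau since event onset."""
    if spec.family == "rectangular":
        return spec.amplitude if tau < spec.rise + spec.plateau else 0.0
    if spec.family == "triangular":
        if tau < spec.rise:
            return spec.amplitude * (tau / spec.rise if spec.rise > 0 else 1.0)
        tau2 = tau - spec.rise
        if tau2 < spec.decay:
            return spec.amplitude * (1.0 - tau2 / spec.decay)
        return 0.0
    # piecewise-exponential: decay truncated (and renormalized) at 7 time
    # constants so the signal is exactly baseline between events
    if tau < spec.rise:
        return spec.amplitude * (tau / spec.rise if spec.rise > 0 else 1.0)
    t2 = tau - spec.rise
    W = 7.0 * spec.decay
    if t2 >= W:
        return 0.0
    E = math.exp(-W / spec.decay)
    return spec.amplitude * (math.exp(-t2 / spec.decay) - E) / (1.0 - E)


def _ground_truth(spec: WaveformSpec, kind: str) -> dict:
    ms = 1e3
    gt: dict[str, float] = {}
    if kind == "ap":
        gt["APA"] = spec.amplitude
        gt["MDP"] = spec.baseline
        gt["CL"] = spec.period * ms
        if spec.family == "rectangular":
            for x in (10, 30, 40, 50, 70, 80, 90):
                gt[f"APD{x}"] = (spec.rise + spec.plateau) * ms
        elif spec.family == "triangular":
            # linear repolarization crosses x% at x/100 of the decay ramp
            for x in (10, 30, 40, 50, 70, 80, 90):
                gt[f"APD{x}"] = (spec.rise + x / 100.0 * spec.decay) * ms
            gt["Triangulation"] = 1.0
        return gt
    # Ca2+ transient
    gt["FREQ"] = 1.0 / spec.period
    gt["amplitude"] = spec.amplitude
    if spec.family == "triangular":
        gt["RT1050"] = 0.4 * spec.rise * ms
        gt["RT1090"] = 0.8 * spec.rise * ms
        gt["TPEAK"] = 0.9 * spec.rise * ms
        gt["DT9010"] = 0.8 * spec.decay * ms
        gt["DURATION"] = (0.9 * spec.rise + 0.9 * spec.decay) * ms
    elif spec.family == "piecewise-exponential":
        gt["RT1050"] = 0.4 * spec.rise * ms
        gt["RT1090"] = 0.8 * spec.rise * ms
        gt["TPEAK"] = 0.9 * spec.rise * ms
        # truncated/renormalized decay crosses fraction f of the amplitude
        # at t = -tau ln(f (1 - E) + E), E = exp(-7)
        E = math.exp(-7.0)

        def t_frac(f):
            return -spec.decay * math.log(f * (1.0 - E) + E)

        gt["DT9010"] = (t_frac(0.1) - t_frac(0.9)) * ms
        gt["DURATION"] = (0.9 * spec.rise + t_frac(0.1)) * ms
    return gt


def generate(spec: WaveformSpec, dt: float = 1e-4,
             kind: str = "cat") -> FixtureTrace:
    """Sample an event train and return it with its analytic biomarkers.

    ``kind`` selects the biomarker family for the ground truth: ``"ap"``
    (signal in mV) or ``"cat"`` (signal in concentration/fluorescence
    units).  The trace covers ``count`` periods plus one leading and one
    trailing quiet period so that all events are complete.
    """
    if kind not in ("ap", "cat"):
        raise ValueError("kind must be 'ap' or 'cat'")
    total = (spec.count + 2) * spec.period
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, float(spec.baseline))
    for k in range(spec.count):
        onset = (k + 1) * spec.period
        sel = (t >= onset) & (t < onset + spec.period)
        tau = t[sel] - onset
        v[sel] += np.array([_event_value(spec, x) for x in tau])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    return FixtureTrace(t=t, signal=v, kind=kind,
                        ground_truth=_ground_truth(spec, kind))


def inject_dad(trace: FixtureTrace, time: float, amplitude: float,
               width: float = 0.05, *,
               diastolic_level: float = -40.0) -> FixtureTrace:
    """Add a smooth diastolic bump (mV) to an AP-like fixture trace.

    ``time`` must fall in a diastolic interval (signal below
    ``diastolic_level`` mV); a Gaussian bump of the given peak amplitude and
    width (s, standard deviation) is added and the ground-truth event
    recorded on the returned copy.
    """
    if trace.kind != "ap":
        raise ValueError("DAD injection requires an AP-like trace")
    i = int(np.searchsorted(trace.t, time))
    if i >= len(trace.t) or trace.signal[i] >= diastolic_level:
        raise ValueError(
            f"t={time:.3f} s is not in a diastolic interval "
            f"(signal >= {diastolic_level} mV)")
    bump = amplitude * np.exp(-0.5 * ((trace.t - time) / width) ** 2)
    out = FixtureTrace(t=trace.t.copy(), signal=trace.signal + bump,
                       kind=trace.kind, ground_truth=dict(trace.ground_truth),
                       events=list(trace.events))
    out.events.append({"time": time, "amplitude": amplitude, "width": width})
    return out
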