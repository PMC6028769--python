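"""Action-potential and Ca2+-transient biomarker extraction.

Eight AP biomarkers (APA, MDP, CL, Vmax, APD10/30/90, Triangulation; APD40/
50/70/80 computed internally) and six Ca2+-transient biomarkers (DURATION,
TPEAK, RT1050, RT1090, DT9010, FREQ) are measured per event and averaged over
all complete events in the trace.  Conventions:

* APDx is measured from the maximum-upstroke-velocity instant to the crossing
  of x% repolarization on the span peak-to-MDP, linearly interpolated.
* CL is the interval between successive maximum-dV/dt instants.
* Ca2+-transient amplitude is diastolic minimum to peak; rise/decay times are
  between amplitude fractions on the rising/decaying limb; DURATION spans the
  10%-amplitude up-crossing to the 10%-amplitude down-crossing; TPEAK runs
  from the 10%-amplitude up-crossing to the peak.  All fraction-based Ca2+
  biomarkers are well defined on uncalibrated (fluorescence) signals.

Potentials are reported in mV, durations in ms, upstroke velocity in V/s,
rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "APBiomarkers", "CaTBiomarkers", "DADEvent", "InsufficientDataError",
    "ap_biomarkers", "cat_biomarkers", "triangulation", "classify_ap",
    "detect_dads", "detect_premature_releases", "BiomarkerSet",
]

#: repolarization fractions extracted per AP
_APD_FRACTIONS = (10, 30, 40, 50, 70, 80, 90)


class InsufficientDataError(ValueError):
    """Raised when a trace contains too few complete events."""


@dataclass
class APBiomarkers:
    APA: float       # mV
    MDP: float       # mV
    CL: float        # ms
    Vmax: float      # V/s
    APD10: float     # ms
    APD30: float     # ms
    APD40: float     # ms
    APD50: float     # ms
    APD70: float     # ms
    APD80: float     # ms
    APD90: float     # ms
    triangulation: float
    n_aps: int                # complete APs analyzed
    n_detected: int = 0       # all detected AP peaks (incl. partial)
    per_ap: dict = field(default_factory=dict, repr=False)

    @property
    def upstroke_times(self) -> np.ndarray:
        return self.per_ap["t_upstroke"]


@dataclass
class CaTBiomarkers:
    DURATION: float  # ms
    TPEAK: float     # ms
    RT1050: float    # ms
    RT1090: float    # ms
    DT9010: float    # ms
    FREQ: float      # Hz
    amplitude: float  # signal units (mM for simulated traces)
    n_transients: int
    per_transient: dict = field(default_factory=dict, repr=False)


@dataclass
class DADEvent:
    """A diastolic depolarization event.

    ``kind`` is ``"dad"`` for a subthreshold delayed afterdepolarization and
    ``"triggered_ap"`` for a depolarization reaching the AP threshold (or a
    premature full AP).
    """

    time: float       # s
    amplitude: float  # mV above the local diastolic baseline
    kind: str


def _as_t_v(trace, attr: str):
    """Accept a Trace or a (t, values) pair."""
    if hasattr(trace, "t") and hasattr(trace, attr):
        return np.asarray(trace.t, float), np.asarray(getattr(trace, attr), float)
    t, v = trace
    return np.asarray(t, float), np.asarray(v, float)


def _cross_time(t, v, level, i0, i1, direction):
    """Linear-interpolated time where v crosses level within [i0, i1]."""
    seg = v[i0:i1 + 1]
    if direction == "down":
        hits = np.flatnonzero((seg[:-1] > level) & (seg[1:] <= level))
    else:
        hits = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    if len(hits) == 0:
        return None
    k = i0 + hits[0]
    v0, v1 = v[k], v[k + 1]
    if v1 == v0:
        return t[k]
    frac = (level - v0) / (v1 - v0)
    return t[k] + frac * (t[k + 1] - t[k])


def _find_ap_peaks(vm_mV: np.ndarray, dt_ms: float,
                   peak_height: float, prominence: float) -> np.ndarray:
    distance = max(int(round(50.0 / dt_ms)), 1)  # APs at least 50 ms apart
    peaks, _ = find_peaks(vm_mV, height=peak_height,
                          prominence=prominence, distance=distance)
    return peaks


def ap_biomarkers(trace, *, peak_height: float = 0.0,
                  prominence: float = 40.0) -> APBiomarkers:
    """Extract AP biomarkers from a trace (per-AP values + means).

    ``peak_height`` (mV) and ``prominence`` (mV) control AP detection.
    Raises :class:`InsufficientDataError` with fewer than 2 complete APs.
    """
    t_s, vm_V = _as_t_v(trace, "Vm")
    t = t_s * 1e3          # ms
    vm = vm_V * 1e3        # mV
    if len(t) < 3:
        raise InsufficientDataError("trace too short")
    dt = float(np.median(np.diff(t)))
    dvdt = np.gradient(vm, t)  # mV/ms == V/s

    peaks = _find_ap_peaks(vm, dt, peak_height, prominence)
    if len(peaks) < 3:
        raise InsufficientDataError(
            f"need >= 3 detected APs for complete-event analysis, "
            f"got {len(peaks)}")

    rows = {k: [] for k in
            ("t_peak", "t_upstroke", "t_mdp", "APA", "MDP", "Vmax",
             *(f"APD{x}" for x in _APD_FRACTIONS))}
    # complete APs: have both a preceding and a following inter-AP minimum
    for i in range(1, len(peaks) - 1):
        p_prev, p, p_next = peaks[i - 1], peaks[i], peaks[i + 1]
        i_mdp_prev = p_prev + int(np.argmin(vm[p_prev:p]))
        i_mdp_next = p + int(np.argmin(vm[p:p_next]))
        mdp = vm[i_mdp_next]
        vpeak = vm[p]
        apa = vpeak - mdp
        i_up = i_mdp_prev + int(np.argmax(dvdt[i_mdp_prev:p + 1]))
        rows["t_peak"].append(t[p])
        rows["t_upstroke"].append(t[i_up])
        rows["t_mdp"].append(t[i_mdp_next])
        rows["APA"].append(apa)
        rows["MDP"].append(mdp)
        rows["Vmax"].append(float(dvdt[i_up]))
        for x in _APD_FRACTIONS:
            level = vpeak - x / 100.0 * apa
            tc = _cross_time(t, vm, level, p, i_mdp_next, "down")
            rows[f"APD{x}"].append(
                np.nan if tc is None else tc - t[i_up])

    per_ap = {k: np.asarray(v, float) for k, v in rows.items()}
    if len(per_ap["t_peak"]) < 1:
        raise InsufficientDataError("no complete APs")
    cl = np.diff(per_ap["t_upstroke"])
    if len(cl) == 0:
        # fall back to peak intervals when only one complete AP is bracketed
        cl = np.diff(per_ap["t_peak"])
    means = {k: float(np.nanmean(per_ap[k]))
             for k in per_ap if k.startswith(("APA", "MDP", "Vmax", "APD"))}
    tri = triangulation(means["APD30"], means["APD40"],
                        means["APD70"], means["APD80"])
    return APBiomarkers(
        APA=means["APA"], MDP=means["MDP"],
        CL=float(np.mean(cl)) if len(cl) else np.nan,
        Vmax=means["Vmax"],
        APD10=means["APD10"], APD30=means["APD30"], APD40=means["APD40"],
        APD50=means["APD50"], APD70=means["APD70"], APD80=means["APD80"],
        APD90=means["APD90"], triangulation=tri,
        n_aps=len(per_ap["t_peak"]), n_detected=len(peaks), per_ap=per_ap)


def triangulation(apd30: float, apd40: float, apd70: float,
                  apd80: float) -> float:
    """AP shape factor (APD30-APD40)/(APD70-APD80).

    > 1.5 classifies ventricular-like, < 1.5 atrial-like.
    """
    denom = apd70 - apd80
    if abs(denom) <= 1e-9:
        raise ValueError("triangulation undefined: APD70 == APD80")
    return (apd30 - apd40) / denom


def classify_ap(tri: float) -> str:
    return "ventricular-like" if tri > 1.5 else "atrial-like"


def cat_biomarkers(trace, *, rel_prominence: float = 0.25) -> CaTBiomarkers:
    """Extract Ca2+-transient biomarkers (per-transient values + means).

    Transients are detected as peaks with prominence at least
    ``rel_prominence`` times the global signal excursion.  Raises
    :class:`InsufficientDataError` on monotone or quiescent signals.
    """
    t_s, ca = _as_t_v(trace, "Ca_i")
    t = t_s * 1e3  # ms
    span = float(np.max(ca) - np.min(ca)) if len(ca) else 0.0
    if span <= 0:
        raise InsufficientDataError("flat Ca2+ signal")
    dt = float(np.median(np.diff(t)))
    distance = max(int(round(100.0 / dt)), 1)
    peaks, _ = find_peaks(ca, prominence=rel_prominence * span,
                          distance=distance)
    if len(peaks) < 3:
        raise InsufficientDataError(
            f"need >= 3 detected transients, got {len(peaks)}")

    rows = {k: [] for k in ("t_peak", "amplitude", "DURATION", "TPEAK",
                            "RT1050", "RT1090", "DT9010")}
    for i in range(1, len(peaks) - 1):
        p_prev, p, p_next = peaks[i - 1], peaks[i], peaks[i + 1]
        i_min_prev = p_prev + int(np.argmin(ca[p_prev:p]))
        i_min_next = p + int(np.argmin(ca[p:p_next]))
        base = ca[i_min_prev]
        amp = ca[p] - base
        if amp <= 0:
            continue

        def up(frac):
            return _cross_time(t, ca, base + frac * amp, i_min_prev, p, "up")

        def down(frac):
            return _cross_time(t, ca, base + frac * amp, p, i_min_next, "down")

        t10u, t50u, t90u = up(0.10), up(0.50), up(0.90)
        t90d, t10d = down(0.90), down(0.10)
        if None in (t10u, t50u, t90u, t90d, t10d):
            continue
        rows["t_peak"].append(t[p])
        rows["amplitude"].append(amp)
        rows["TPEAK"].append(t[p] - t10u)
        rows["RT1050"].append(t50u - t10u)
        rows["RT1090"].append(t90u - t10u)
        rows["DT9010"].append(t10d - t90d)
        rows["DURATION"].append(t10d - t10u)

    per = {k: np.asarray(v, float) for k, v in rows.items()}
    if len(per["t_peak"]) < 1:
        raise InsufficientDataError("no complete Ca2+ transients")
    intervals = np.diff(np.asarray(t)[peaks])  # use all peaks for rate
    freq = 1000.0 / float(np.mean(intervals))
    return CaTBiomarkers(
        DURATION=float(np.mean(per["DURATION"])),
        TPEAK=float(np.mean(per["TPEAK"])),
        RT1050=float(np.mean(per["RT1050"])),
        RT1090=float(np.mean(per["RT1090"])),
        DT9010=float(np.mean(per["DT9010"])),
        FREQ=freq, amplitude=float(np.mean(per["amplitude"])),
        n_transients=len(per["t_peak"]), per_transient=per)


class BiomarkerSet(dict):
    """Name -> value mapping of the 14 calibration biomarkers."""

    @classmethod
    def from_traces(cls, ap: APBiomarkers, cat: CaTBiomarkers) -> "BiomarkerSet":
        return cls({
            "APA": ap.APA, "MDP": ap.MDP, "CL": ap.CL, "Vmax": ap.Vmax,
            "APD10": ap.APD10, "APD30": ap.APD30, "APD90": ap.APD90,
            "Triangulation": ap.triangulation,
            "DURATION": cat.DURATION, "TPEAK": cat.TPEAK,
            "RT1050": cat.RT1050, "RT1090": cat.RT1090,
            "DT9010": cat.DT9010, "FREQ": cat.FREQ,
        })


def detect_dads(trace, *, amplitude_threshold: float = 1.0,
                ap_threshold: float = -20.0,
                premature_fraction: float = 0.65,
                diastolic_level: float = -40.0,
                reference_cl: float | None = None) -> list[DADEvent]:
    """Detect delayed afterdepolarizations and triggered premature beats.

    A DAD is a local Vm elevation during diastole (Vm below
    ``diastolic_level`` mV) whose prominence exceeds ``amplitude_threshold``
    mV but stays below ``ap_threshold`` mV; a diastolic depolarization
    reaching ``ap_threshold`` is a triggered AP, as is a full AP whose cycle
    length is shorter than ``premature_fraction`` times the reference cycle
    length (``reference_cl`` seconds if given, e.g. from a control arm,
    otherwise the trace's own median cycle).
    """
    t_s, vm_V = _as_t_v(trace, "Vm")
    t = t_s  # s
    vm = vm_V * 1e3  # mV
    dt_ms = float(np.median(np.diff(t))) * 1e3
    events: list[DADEvent] = []

    peaks = _find_ap_peaks(vm, dt_ms, 0.0, 40.0)
    # premature full APs
    if len(peaks) >= 3:
        tp = t[peaks]
        cls_ = np.diff(tp)
        ref = np.median(cls_) if reference_cl is None else reference_cl
        for k, c in enumerate(cls_):
            if c < premature_fraction * ref:
                events.append(DADEvent(time=float(tp[k + 1]),
                                       amplitude=float(vm[peaks[k + 1]]
                                                       - np.min(vm)),
                                       kind="triggered_ap"))

    # diastolic interval per AP pair: from the end of repolarization (first
    # sample below diastolic_level after the peak) to the start of the next
    # upstroke (last sample below diastolic_level before the next peak);
    # bumps inside it may rise above diastolic_level without being APs
    if len(peaks) >= 2:
        bounds = []
        for p0, p1 in zip(peaks[:-1], peaks[1:]):
            below = np.flatnonzero(vm[p0:p1] < diastolic_level)
            if len(below) < 3:
                continue
            bounds.append((p0 + below[0], p0 + below[-1]))
    else:
        below = np.flatnonzero(vm < diastolic_level)
        bounds = [(below[0], below[-1])] if len(below) >= 3 else []

    min_sep = max(int(round(20.0 / dt_ms)), 1)
    for i0, i1 in bounds:
        seg = vm[i0:i1 + 1]
        bumps, props = find_peaks(seg, prominence=amplitude_threshold,
                                  distance=min_sep)
        for b, prom in zip(bumps, props["prominences"]):
            peak_v = seg[b]
            kind = "triggered_ap" if peak_v >= ap_threshold else "dad"
            events.append(DADEvent(time=float(t[i0 + b]),
                                   amplitude=float(prom), kind=kind))
    events.sort(key=lambda e: e.time)
    return events


def detect_premature_releases(trace, *, rel_prominence: float = 0.008,
                              main_fraction: float = 0.4) -> list[float]:
    """Times (s) of diastolic sub-transient Ca2+ release events.

    Secondary Ca2+ peaks whose prominence exceeds ``rel_prominence`` of the
    global excursion but stays below ``main_fraction`` of it are classified
    as premature releases (the hallmark of leaky/immature RyR gating).
    """
    t, ca = _as_t_v(trace, "Ca_i")
    span = float(np.max(ca) - np.min(ca))
    if span <= 0:
        return []
    dt_ms = float(np.median(np.diff(t))) * 1e3
    distance = max(int(round(50.0 / dt_ms)), 1)
    peaks, props = find_peaks(ca, prominence=rel_prominence * span,
                              distance=distance)
    out = []
    for p, prom in zip(peaks, props["prominences"]):
        if prom < main_fraction * span:
            out.append(float(t[p]))
    return out
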