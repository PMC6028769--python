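"""One-command reproduction harness for the validation experiments.

Each ``reproduce_*`` function runs a complete protocol — spontaneous
steady-state biomarkers, current-block arms, afterdepolarization protocols,
ionic-environment rate challenges, fast-pacing alternans — and compares the
outcome against the packaged published values with explicit tolerances.

Results are returned as :class:`ExperimentResult` objects whose ``rows``
table carries, per quantity: the simulated value, the published value, the
tolerance, and a pass flag.  Tolerances (3% relative for steady-state
biomarkers, 5 percentage points for block arms, 3 points for rate changes,
1 point for the funny-current block) absorb convention-level noise (stimulus
width, analysis windows, biomarker operational definitions) while still
catching transcription errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from . import biomarkers as bm
from . import model
from .optimize import (BiomarkerObjective, load_ranges,
                       published_simulated_biomarkers)
from .parameters import ModelParameters, apply_block, load_parameters, make_immature_ryr
from .simulate import (SPONTANEOUS, Protocol, packaged_steady_state, prerun,
                       run_block_experiment, run_environment_series,
                       run_hypercalcemia_dad, simulate)

__all__ = [
    "ExperimentResult", "TABLE3_ARMS", "CHR_FRACTIONS",
    "reproduce_table2", "reproduce_table3", "reproduce_hypercalcemia_dads",
    "reproduce_immature_ryr", "reproduce_rate_challenges",
    "reproduce_alternans", "reproduce_all",
]


@dataclass
class ExperimentResult:
    experiment: str
    rows: pd.DataFrame
    details: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.rows["ok"].all())

    def __str__(self) -> str:  # pragma: no cover - convenience
        status = "PASS" if self.passed else "FAIL"
        return f"[{status}] {self.experiment}\n{self.rows.to_string(index=False)}"


# drug, dose label, block map, stimulus pA, biomarker, published relative
# change (%), published experimental change mean +/- SD (%)
TABLE3_ARMS: tuple = (
    ("TTX", "3 uM", {"G_Na": 0.18}, 750.0, "Vmax", 25.2, (41.2, 11.2)),
    ("TTX", "10 uM", {"G_Na": 0.06}, 750.0, "Vmax", 22.9, (16.7, 1.8)),
    ("TTX", "30 uM", {"G_Na": 0.02}, 750.0, "Vmax", 19.4, (16.8, 2.0)),
    ("E4031", "30 nM", {"G_Kr": 0.77}, 550.0, "APD50", 124.9, (109.1, 3.7)),
    ("E4031", "100 nM", {"G_Kr": 0.50}, 550.0, "APD50", 175.1, (113.4, 3.9)),
    ("E4031", "30 nM", {"G_Kr": 0.77}, 550.0, "APD90", 123.4, (140.3, 7.6)),
    ("E4031", "100 nM", {"G_Kr": 0.50}, 550.0, "APD90", 171.6, (170.4, 13.6)),
    ("NIFED", "3 nM", {"G_CaL": 0.93}, 550.0, "APD50", 95.3, (84.6, 2.4)),
    ("NIFED", "10 nM", {"G_CaL": 0.79}, 550.0, "APD50", 85.2, (70.3, 6.1)),
    ("NIFED", "30 nM", {"G_CaL": 0.56}, 550.0, "APD50", 65.3, (65.7, 3.0)),
    ("NIFED", "100 nM", {"G_CaL": 0.28}, 550.0, "APD50", 37.7, (45.4, 4.5)),
    ("NIFED", "3 nM", {"G_CaL": 0.93}, 550.0, "APD90", 95.9, (89.4, 1.0)),
    ("NIFED", "10 nM", {"G_CaL": 0.79}, 550.0, "APD90", 86.2, (78.4, 4.4)),
    ("NIFED", "30 nM", {"G_CaL": 0.56}, 550.0, "APD90", 67.7, (74.0, 2.3)),
    ("NIFED", "100 nM", {"G_CaL": 0.28}, 550.0, "APD90", 42.6, (58.2, 5.4)),
)

#: IC50-based block fractions are not used for CHR; a range of G_Ks blocks
#: is screened and only "little effect on APD90" is asserted.
CHR_FRACTIONS: tuple = (0.7, 0.5, 0.3, 0.1)

# IC50 values recorded for provenance; blocks are applied with the printed
# remaining-conductance fractions, not through a Hill mapping.
IC50_uM = {"TTX": 0.64, "NIFED": 0.038, "E4031": 0.1}


def reproduce_table2(*, pre_run: float = 800.0, window: float = 20.0,
                     tolerance: float = 0.03,
                     pre_state: np.ndarray | None = None,
                     rtol: float = 1e-7, atol: float = 1e-9) -> ExperimentResult:
    """Spontaneous steady-state biomarkers vs the published simulated column.

    Each of the 14 biomarkers must match the published value within
    ``tolerance`` (relative) and lie inside the experimental mean +/- SD
    band.
    """
    params = load_parameters("paci2018-optimized")
    if pre_state is None:
        pre_state = prerun(params, SPONTANEOUS, model.default_initial_state(),
                           pre_run, rtol=rtol, atol=atol)
    trace = simulate(params, SPONTANEOUS, pre_state, window, t0=pre_run,
                     rtol=rtol, atol=atol)
    ap = bm.ap_biomarkers(trace)
    cat = bm.cat_biomarkers(trace)
    sim = bm.BiomarkerSet.from_traces(ap, cat)
    published = published_simulated_biomarkers()
    ranges = {r.name: r for r in load_ranges()}
    rows = []
    for name, value in sim.items():
        pub = published[name]
        r = ranges[name]
        rel = abs(value - pub) / abs(pub)
        in_band = abs(value - r.mean) <= r.sd
        rows.append({
            "biomarker": name, "units": r.units, "simulated": value,
            "published": pub, "rel_err": rel, "in_band": in_band,
            "provenance": "table2",
            "ok": bool(rel <= tolerance and in_band),
        })
    return ExperimentResult("table2", pd.DataFrame(rows),
                            details={"trace_window": window,
                                     "triangulation_class":
                                         bm.classify_ap(ap.triangulation)})


def reproduce_table3(*, pre_run: float = 800.0, drug_run: float = 400.0,
                     tolerance_points: float = 5.0,
                     chr_apd90_band: float = 10.0,
                     pre_state: np.ndarray | None = None,
                     rtol: float = 1e-7, atol: float = 1e-9) -> ExperimentResult:
    """Current-block arms vs the published relative-change column.

    Runs the 15 tabulated arm/biomarker combinations (three TTX doses on
    Vmax; two E4031 and four nifedipine doses on APD50 and APD90) plus the
    G_Ks screen, asserting |simulated - published| <= ``tolerance_points``
    percentage points, monotone dose-response along the nifedipine and E4031
    series, and |APD90 change| < ``chr_apd90_band`` points for the G_Ks
    screen.
    """
    params = load_parameters("paci2018-optimized")
    if pre_state is None:
        protocol = Protocol(mode="paced", pacing_rate=1.0)
        pre_state = prerun(params, protocol, model.default_initial_state(),
                           pre_run, rtol=rtol, atol=atol)
    rows = []
    cache: dict = {}
    for drug, dose, block, stim, bio, pub, exp in TABLE3_ARMS:
        key = (tuple(sorted(block.items())), stim)
        if key not in cache:
            cache[key] = run_block_experiment(
                params, block, stim, drug_run=drug_run,
                pre_state=pre_state, rtol=rtol, atol=atol)
        res = cache[key]
        value = res.changes[bio]
        rows.append({
            "drug": drug, "dose": dose, "biomarker": bio,
            "block": "; ".join(f"{k}={v:g}" for k, v in block.items()),
            "simulated_pct": value, "published_pct": pub,
            "experimental_pct": f"{exp[0]} +/- {exp[1]}",
            "capture": res.capture_blocked, "provenance": "table3",
            "ok": bool(abs(value - pub) <= tolerance_points),
        })
    for frac in CHR_FRACTIONS:
        res = run_block_experiment(params, {"G_Ks": frac}, 550.0,
                                   drug_run=drug_run, pre_state=pre_state,
                                   rtol=rtol, atol=atol)
        value = res.changes["APD90"]
        rows.append({
            "drug": "CHR", "dose": f"{100 * (1 - frac):.0f}% block",
            "biomarker": "APD90",
            "block": f"G_Ks={frac:g}", "simulated_pct": value,
            "published_pct": np.nan, "experimental_pct": "little effect",
            "capture": res.capture_blocked, "provenance": "table3",
            "ok": bool(abs(value - 100.0) < chr_apd90_band),
        })
    df = pd.DataFrame(rows)

    def series(drug, biomarker):
        sel = df[(df.drug == drug) & (df.biomarker == biomarker)
                 & df.published_pct.notna()]
        return sel.simulated_pct.to_numpy()

    monotone = {
        "NIFED_APD50_decreasing": bool(np.all(np.diff(series("NIFED", "APD50")) < 0)),
        "NIFED_APD90_decreasing": bool(np.all(np.diff(series("NIFED", "APD90")) < 0)),
        "E4031_APD90_increasing": bool(np.all(np.diff(series("E4031", "APD90")) > 0)),
    }
    return ExperimentResult("table3", df, details={"monotone": monotone})


def _dad_events(trace, reference_cl):
    return bm.detect_dads(trace, reference_cl=reference_cl)


def reproduce_hypercalcemia_dads(*, duration: float = 60.0,
                                 pre_state: np.ndarray | None = None,
                                 rtol: float = 1e-7,
                                 atol: float = 1e-9) -> ExperimentResult:
    """Ca2+-overload afterdepolarizations: overload arm vs control arm.

    Raising extracellular Ca2+ to 3.945 mM must produce subthreshold DADs
    (with events inside the 14-30 s post-switch window) and at least one
    triggered/anticipated beat; the 1.8 mM control arm must stay clean.  A
    paced variant at a basal rate raised by 50% (57 bpm) must still show
    DADs.
    """
    params = load_parameters("paci2018-optimized")
    if pre_state is None:
        pre_state = prerun(params, SPONTANEOUS, model.default_initial_state(),
                           800.0, rtol=rtol, atol=atol)
    control = run_hypercalcemia_dad(params, Ca_o=1.8, duration=duration,
                                    pre_state=pre_state, rtol=rtol, atol=atol)
    ref_cl = bm.ap_biomarkers(control).CL / 1e3
    overload = run_hypercalcemia_dad(params, duration=duration,
                                     pre_state=pre_state, rtol=rtol, atol=atol)
    ctrl_events = _dad_events(control, ref_cl)
    over_events = _dad_events(overload, ref_cl)
    sub = [e for e in over_events if e.kind == "dad"]
    trig = [e for e in over_events if e.kind == "triggered_ap"]
    paced = run_hypercalcemia_dad(params, duration=40.0,
                                  pacing_rate=57.0 / 60.0,
                                  pre_state=pre_state, rtol=rtol, atol=atol)
    paced_events = _dad_events(paced, ref_cl)

    rows = pd.DataFrame([
        {"check": "control_clean", "value": len(ctrl_events),
         "provenance": "results-dads", "ok": len(ctrl_events) == 0},
        {"check": "subthreshold_dads_present", "value": len(sub),
         "provenance": "results-dads", "ok": len(sub) >= 1},
        {"check": "dads_in_14_30_s", "value":
            sum(14.0 <= e.time <= 30.0 for e in sub),
         "provenance": "results-dads",
         "ok": any(14.0 <= e.time <= 30.0 for e in sub)},
        {"check": "triggered_event_present", "value": len(trig),
         "provenance": "results-dads", "ok": len(trig) >= 1},
        {"check": "paced_57bpm_dads", "value": len(paced_events),
         "provenance": "results-dads", "ok": len(paced_events) >= 1},
    ])
    return ExperimentResult("hypercalcemia-dads", rows,
                            details={"events": over_events,
                                     "reference_cl_s": ref_cl})


def paced_diastolic_bump(trace, pacing_rate: float = 1.0, *,
                         dia_start: float = 0.55, dia_end: float = 0.995,
                         trend_window_s: float = 0.3,
                         min_prominence: float = 0.05) -> float:
    """Largest detrended diastolic Vm bump (mV) in a paced trace.

    For each pacing cycle the diastolic segment (fractions of the cycle) is
    detrended with a moving average (removing the slow pacemaker
    depolarization) and scanned for local maxima; returns the maximum bump
    prominence over all cycles (0 when none).
    """
    t = np.asarray(trace.t) - trace.t[0]
    vm = np.asarray(trace.Vm) * 1e3
    dt = float(np.median(np.diff(t)))
    period = 1.0 / pacing_rate
    out = 0.0
    n_cycles = int(np.floor(t[-1] / period))
    win = max(int(round(trend_window_s / dt)), 3)
    for k in range(n_cycles):
        sel = (t >= k * period + dia_start * period) & \
              (t < k * period + dia_end * period)
        seg = vm[sel]
        if len(seg) < win // 2:
            continue
        resid = seg - uniform_filter1d(seg, size=win, mode="nearest")
        peaks, props = find_peaks(resid, prominence=min_prominence)
        if len(peaks):
            out = max(out, float(props["prominences"].max()))
    return out


def reproduce_immature_ryr(*, settle: float = 60.0, window: float = 20.0,
                           dad_threshold: float = 0.5,
                           pre_state: np.ndarray | None = None,
                           rtol: float = 1e-7,
                           atol: float = 1e-9) -> ExperimentResult:
    """Immature RyR gating: premature Ca2+ releases and I_NaCa-block DADs.

    The immature variant (shifted open/closed half-activations, slower
    opening, faster closing) must produce premature diastolic Ca2+ releases
    at normal extracellular Ca2+.  Under 1 Hz pacing, DADs (detrended
    diastolic Vm bumps above ``dad_threshold`` mV) must be present without
    Na+/Ca2+-exchanger block and absent at 70-90% block; the published
    amplitude increase at 50% block is also evaluated.
    """
    params = load_parameters("paci2018-optimized")
    imm = make_immature_ryr(params)
    if pre_state is None:
        pre_state = prerun(params, SPONTANEOUS, model.default_initial_state(),
                           800.0, rtol=rtol, atol=atol)
    # spontaneous arm (normal Ca_o): premature Ca2+ releases
    y = prerun(imm, SPONTANEOUS, pre_state, settle, rtol=rtol, atol=atol)
    spont = simulate(imm, SPONTANEOUS, y, window, t0=settle,
                     rtol=rtol, atol=atol, dt_out=2e-4)
    releases = bm.detect_premature_releases(spont)

    # paced arms with graded I_NaCa block
    proto = Protocol(mode="paced", pacing_rate=1.0, stim_amplitude_pA=550.0)
    paced_ss = packaged_steady_state("paced-1hz")
    bump = {}
    for frac in (1.0, 0.5, 0.3, 0.1):
        p = imm if frac == 1.0 else imm.with_values(
            I_NaCa_max=imm.I_NaCa_max * frac)
        yb = prerun(p, proto, paced_ss, settle, rtol=rtol, atol=atol)
        tr = simulate(p, proto, yb, window, t0=settle,
                      rtol=rtol, atol=atol, dt_out=1e-3)
        bump[frac] = paced_diastolic_bump(tr)

    rows = pd.DataFrame([
        {"check": "premature_ca_releases", "value": len(releases),
         "provenance": "figure7", "ok": len(releases) >= 1},
        {"check": "dads_no_block", "value": bump[1.0],
         "provenance": "supp-inaca-block", "ok": bump[1.0] > dad_threshold},
        {"check": "dad_amplitude_increases_at_50pct", "value": bump[0.5],
         "provenance": "supp-inaca-block", "ok": bump[0.5] > bump[1.0]},
        {"check": "no_dads_at_30pct", "value": bump[0.3],
         "provenance": "supp-inaca-block", "ok": bump[0.3] < dad_threshold},
        {"check": "no_dads_at_10pct", "value": bump[0.1],
         "provenance": "supp-inaca-block", "ok": bump[0.1] < dad_threshold},
    ])
    return ExperimentResult("immature-ryr", rows,
                            details={"bumps_mV": bump,
                                     "n_releases": len(releases)})


def reproduce_rate_challenges(*, pre_state: np.ndarray | None = None,
                              rtol: float = 1e-7,
                              atol: float = 1e-9) -> ExperimentResult:
    """Spontaneous-rate response to funny-current block and ionic changes.

    Four published observations: 3 uM ivabradine (59% G_f remaining) slows
    the spontaneous AP rate by ~2.3% (tolerance 1 point); K_o = 8 and 16 mM
    drop the Ca2+-transient rate by ~11% and ~15% (3 points); K_o = 20 mM
    stops spontaneous activity; Ca_o = 0.1 mM drops the rate by ~17%
    (3 points).
    """
    params = load_parameters("paci2018-optimized")
    if pre_state is None:
        pre_state = prerun(params, SPONTANEOUS, model.default_initial_state(),
                           800.0, rtol=rtol, atol=atol)
    series = run_environment_series(
        params, [{"K_o": 8.0}, {"K_o": 16.0}, {"K_o": 20.0}, {"Ca_o": 0.1}],
        pre_state=pre_state, rtol=rtol, atol=atol)
    iva = run_environment_series(apply_block(params, {"G_f": 0.59}), [],
                                 pre_state=pre_state, rtol=rtol, atol=atol)
    base_rate = series[0]["rate"]
    iva_change = 100.0 * (iva[0]["rate"] - base_rate) / base_rate
    by_key = {tuple(r["override"].items()): r for r in series}

    def drop(key):
        r = by_key[(key,)]
        return None if r["change_pct"] is None else -r["change_pct"]

    rows = pd.DataFrame([
        {"arm": "ivabradine_Gf59", "value_pct": iva_change,
         "published_pct": -2.3, "tol_points": 1.0,
         "provenance": "results-text",
         "ok": abs(iva_change - (-2.3)) <= 1.0},
        {"arm": "K_o_8mM_drop", "value_pct": drop(("K_o", 8.0)),
         "published_pct": 11.0, "tol_points": 3.0,
         "provenance": "results-text",
         "ok": abs(drop(("K_o", 8.0)) - 11.0) <= 3.0},
        {"arm": "K_o_16mM_drop", "value_pct": drop(("K_o", 16.0)),
         "published_pct": 15.0, "tol_points": 3.0,
         "provenance": "results-text",
         "ok": abs(drop(("K_o", 16.0)) - 15.0) <= 3.0},
        {"arm": "K_o_20mM_stops", "value_pct": by_key[(("K_o", 20.0),)]["rate"],
         "published_pct": np.nan, "tol_points": np.nan,
         "provenance": "results-text",
         "ok": by_key[(("K_o", 20.0),)]["rate"] is None},
        {"arm": "Ca_o_0.1mM_drop", "value_pct": drop(("Ca_o", 0.1)),
         "published_pct": 17.0, "tol_points": 3.0,
         "provenance": "results-text",
         "ok": abs(drop(("Ca_o", 0.1)) - 17.0) <= 3.0},
    ])
    return ExperimentResult("rate-challenges", rows,
                            details={"baseline_rate_Hz": base_rate})


def stimulus_response_amplitudes(trace, pacing_rate: float) -> np.ndarray:
    """Peak Vm (mV) reached after each stimulus of a paced trace."""
    t = np.asarray(trace.t) - trace.t[0]
    vm = np.asarray(trace.Vm) * 1e3
    period = 1.0 / pacing_rate
    n = int(np.floor(t[-1] / period))
    return np.array([vm[(t >= k * period) & (t < (k + 1) * period)].max()
                     for k in range(n)])


def reproduce_alternans(*, pacing_rate: float = 2.0, settle: float = 60.0,
                        window: float = 10.0, threshold_mV: float = 10.0,
                        rtol: float = 1e-7, atol: float = 1e-9) -> ExperimentResult:
    """Fast pacing (120 bpm) produces an alternans-like response pattern.

    The membrane response must alternate beat-to-beat (a full AP followed by
    a smaller response), quantified as the mean absolute difference between
    consecutive per-stimulus peak potentials exceeding ``threshold_mV``.
    """
    params = load_parameters("paci2018-optimized")
    proto = Protocol(mode="paced", pacing_rate=pacing_rate,
                     stim_amplitude_pA=550.0)
    y = prerun(params, proto, packaged_steady_state("paced-1hz"), settle,
               rtol=rtol, atol=atol)
    tr = simulate(params, proto, y, window, t0=settle,
                  rtol=rtol, atol=atol, dt_out=1e-3)
    amps = stimulus_response_amplitudes(tr, pacing_rate)
    alt = float(np.mean(np.abs(np.diff(amps))))
    rows = pd.DataFrame([
        {"check": "beat_to_beat_alternation_mV", "value": alt,
         "provenance": "supp-alternans", "ok": alt > threshold_mV},
    ])
    return ExperimentResult("alternans-2hz", rows,
                            details={"per_stimulus_peaks_mV": amps})


def reproduce_all(**kwargs) -> dict[str, ExperimentResult]:
    """Run every experiment; returns a name -> result mapping."""
    params = load_parameters("paci2018-optimized")
    spont = prerun(params, SPONTANEOUS, model.default_initial_state(), 800.0)
    paced = packaged_steady_state("paced-1hz")
    return {
        "table2": reproduce_table2(pre_state=spont),
        "table3": reproduce_table3(pre_state=paced),
        "dads": reproduce_hypercalcemia_dads(pre_state=spont),
        "immature-ryr": reproduce_immature_ryr(pre_state=spont),
        "rates": reproduce_rate_challenges(pre_state=spont),
        "alternans": reproduce_alternans(),
    }
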