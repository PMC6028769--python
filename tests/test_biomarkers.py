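"""Biomarker extraction against closed-form synthetic waveforms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hipsccm as hp
from hipsccm.biomarkers import (InsufficientDataError, ap_biomarkers,
                                cat_biomarkers, classify_ap, detect_dads,
                                triangulation)
from hipsccm.fixtures import WaveformSpec, generate, inject_dad

TOL_MS = 0.5
TOL_MV = 0.1


class TestAPOracle:
    def test_rectangular_train(self):
        spec = WaveformSpec(family="rectangular", baseline=-75.0,
                            amplitude=100.0, plateau=0.3, period=1.0,
                            count=6)
        tr = generate(spec, kind="ap")
        ap = ap_biomarkers(tr)
        gt = tr.ground_truth
        assert ap.APA == pytest.approx(gt["APA"], abs=TOL_MV)
        assert ap.MDP == pytest.approx(gt["MDP"], abs=TOL_MV)
        assert ap.CL == pytest.approx(gt["CL"], abs=TOL_MS)
        for x in (10, 30, 90):
            assert getattr(ap, f"APD{x}") == pytest.approx(
                gt[f"APD{x}"], abs=TOL_MS)

    def test_linear_repolarization_uniform_apd_spacing(self):
        # sub-sample rise keeps the upstroke-reference offset below the
        # interpolation tolerance
        spec = WaveformSpec(family="triangular", baseline=-80.0,
                            amplitude=110.0, rise=0.0004, decay=0.35,
                            period=1.0, count=6)
        tr = generate(spec, kind="ap")
        ap = ap_biomarkers(tr)
        # uniform spacing on a linear ramp
        assert (ap.APD30 - ap.APD40) == pytest.approx(
            ap.APD70 - ap.APD80, abs=TOL_MS)
        assert ap.triangulation == pytest.approx(1.0, abs=0.02)
        assert classify_ap(ap.triangulation) == "atrial-like"
        for x in (10, 30, 40, 50, 70, 80, 90):
            assert getattr(ap, f"APD{x}") == pytest.approx(
                tr.ground_truth[f"APD{x}"], abs=TOL_MS)

    def test_insufficient_aps(self):
        spec = WaveformSpec(family="rectangular", baseline=-75.0,
                            amplitude=100.0, plateau=0.3, period=1.0,
                            count=1)
        with pytest.raises(InsufficientDataError):
            ap_biomarkers(generate(spec, kind="ap"))

    def test_order_invariant(self, spont_ap):
        ap = spont_ap
        assert ap.APD10 <= ap.APD30 <= ap.APD90


class TestTriangulation:
    def test_linear_ramp_is_one(self):
        assert triangulation(30.0, 40.0, 70.0, 80.0) == pytest.approx(1.0)

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError):
            triangulation(30.0, 40.0, 70.0, 70.0)

    def test_square_ap_is_zero(self):
        assert triangulation(300.0, 300.0, 300.0, 301.0) == pytest.approx(0.0)
        assert classify_ap(0.0) == "atrial-like"

    def test_classification_threshold(self):
        assert classify_ap(1.6) == "ventricular-like"
        assert classify_ap(1.4) == "atrial-like"


class TestCaTOracle:
    def test_triangle_transient(self):
        spec = WaveformSpec(family="triangular", baseline=1e-4,
                            amplitude=1e-3, rise=0.1, decay=0.4,
                            period=1.5, count=6)
        tr = generate(spec, kind="cat")
        cat = cat_biomarkers(tr)
        gt = tr.ground_truth
        assert cat.RT1050 == pytest.approx(gt["RT1050"], abs=TOL_MS)
        assert cat.RT1090 == pytest.approx(gt["RT1090"], abs=TOL_MS)
        assert cat.DT9010 == pytest.approx(gt["DT9010"], abs=TOL_MS)
        assert cat.TPEAK == pytest.approx(gt["TPEAK"], abs=TOL_MS)
        assert cat.DURATION == pytest.approx(gt["DURATION"], abs=TOL_MS)
        assert cat.FREQ == pytest.approx(gt["FREQ"], rel=1e-3)

    def test_one_hz_train(self):
        spec = WaveformSpec(family="piecewise-exponential", baseline=0.0,
                            amplitude=1.0, rise=0.02, decay=0.05,
                            period=1.0, count=6)
        cat = cat_biomarkers(generate(spec, kind="cat"))
        assert cat.FREQ == pytest.approx(1.0, rel=1e-3)

    def test_flat_signal_rejected(self):
        t = np.arange(0, 5, 1e-3)
        with pytest.raises(InsufficientDataError):
            cat_biomarkers((t, np.ones_like(t)))

    def test_order_invariant(self, spont_cat):
        assert spont_cat.RT1050 <= spont_cat.RT1090

    def test_amplitude_relative_biomarkers_scale_free(self):
        """Rescaling an uncalibrated fluorescence-like signal leaves all
        fraction-based biomarkers unchanged."""
        spec = WaveformSpec(family="piecewise-exponential", baseline=0.2,
                            amplitude=1.0, rise=0.08, decay=0.12,
                            period=1.0, count=5)
        tr = generate(spec, kind="cat")
        a = cat_biomarkers(tr)
        scaled = (tr.t, 3.7 * tr.signal + 11.0)
        b = cat_biomarkers(scaled)
        for name in ("RT1050", "RT1090", "DT9010", "TPEAK", "DURATION",
                     "FREQ"):
            assert getattr(a, name) == pytest.approx(getattr(b, name),
                                                     rel=1e-9)


class TestDADDetection:
    def _base_trace(self):
        spec = WaveformSpec(family="triangular", baseline=-78.0,
                            amplitude=112.0, rise=0.002, decay=0.35,
                            period=1.2, count=5)
        return generate(spec, kind="ap")

    def test_flat_diastole_no_events(self):
        assert detect_dads(self._base_trace()) == []

    def test_injected_bump_detected_once(self):
        tr = inject_dad(self._base_trace(), time=2.0, amplitude=3.0)
        events = detect_dads(tr)
        dads = [e for e in events if e.kind == "dad"]
        assert len(dads) == 1
        assert dads[0].time == pytest.approx(2.0, abs=0.005)
        assert dads[0].amplitude == pytest.approx(3.0, abs=0.3)

    def test_subthreshold_bump_ignored(self):
        tr = inject_dad(self._base_trace(), time=2.0, amplitude=0.1)
        assert detect_dads(tr) == []

    def test_large_bump_classified_triggered(self):
        # bump reaching about -10 mV from a -78 mV diastole
        tr = inject_dad(self._base_trace(), time=2.0, amplitude=68.0)
        events = detect_dads(tr)
        assert any(e.kind == "triggered_ap" for e in events)

    def test_injection_inside_ap_rejected(self):
        with pytest.raises(ValueError):
            inject_dad(self._base_trace(), time=1.25, amplitude=3.0)


class TestInterpolationRobustness:
    @given(st.sampled_from([2e-4, 5e-5]))
    def test_sampling_rate_insensitivity(self, dt):
        """Halving/coarsening the sample interval moves fixture biomarkers
        by far less than the interpolation bound."""
        spec = WaveformSpec(family="piecewise-exponential", baseline=1e-4,
                            amplitude=8e-4, rise=0.06, decay=0.15,
                            period=1.4, count=5)
        ref = cat_biomarkers(generate(spec, dt=1e-4, kind="cat"))
        other = cat_biomarkers(generate(spec, dt=dt, kind="cat"))
        for name in ("RT1050", "RT1090", "DT9010", "DURATION"):
            assert getattr(ref, name) == pytest.approx(
                getattr(other, name), abs=TOL_MS)
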