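"""Synthetic waveforms with known biomarkers: testing the measurement code.

Builds a triangular Ca2+-transient train whose biomarkers are known in
closed form, extracts them with the production extractor, and compares.
"""

import hipsccm as hp
from hipsccm.fixtures import WaveformSpec, generate, inject_dad

spec = WaveformSpec(family="triangular", baseline=1e-4, amplitude=1e-3,
                    rise=0.1, decay=0.4, period=1.5, count=6)
trace = generate(spec, kind="cat")
cat = hp.cat_biomarkers(trace)

print("triangular transient: 100 ms linear rise, 400 ms linear decay")
print(f"{'biomarker':10s} {'measured':>9s} {'analytic':>9s}")
for name in ("RT1050", "RT1090", "DT9010", "TPEAK", "DURATION"):
    print(f"{name:10s} {getattr(cat, name):9.1f} "
          f"{trace.ground_truth[name]:9.1f}")
print()

ap_spec = WaveformSpec(family="rectangular", baseline=-75.0, amplitude=100.0,
                       plateau=0.3, period=1.0, count=5)
ap_tr = inject_dad(generate(ap_spec, kind="ap"), time=1.6, amplitude=3.0)
events = hp.detect_dads(ap_tr)
print(f"rectangular AP train with one injected 3 mV diastolic bump:")
print(f"  detected {len(events)} event(s): "
      f"t={events[0].time:.2f} s, {events[0].amplitude:.1f} mV, "
      f"{events[0].kind}")
print()
print("Sub-0.5 ms agreement certifies the extractors independently of the")
print("ODE model; the same thresholds then apply to simulated traces.")
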