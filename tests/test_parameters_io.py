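"""Parameter-set loading, registry semantics and trace/config round-trips."""

import numpy as np
import pytest

import hipsccm as hp
from hipsccm import SPONTANEOUS, load_run_config, read_trace, write_trace
from hipsccm.parameters import (CONDUCTANCE_REGISTRY,
                                OPTIMIZED_PARAMETER_NAMES, load_parameters,
                                save_parameters)


class TestParameterSets:
    def test_optimized_values(self, params):
        assert params.I_NaK_max == 2.6351
        assert params.I_NaCa_max == 3917.0463
        assert params.V_max_up == 0.5113
        assert params.K_up == 3.1928e-4
        assert params.I_leak_max == 4.7279e-4
        assert params.alpha == 2.5371
        assert params.ryr.I_rel_max == 62.5434
        assert params.ryr.a1 == 0.05354
        assert params.ryr.a2 == 0.0488
        assert params.ryr.a_half == 0.02427
        assert params.ryr.o_half == 0.01042
        assert params.ryr.c_half == 0.00144

    def test_baseline_values(self, baseline_params):
        assert baseline_params.V_max_up == 0.56064
        assert baseline_params.I_NaK_max == 2.2958
        assert baseline_params.K_up == 2.5e-4
        assert baseline_params.I_leak_max == 4.444e-4
        assert baseline_params.alpha == 2.8571432

    def test_default_extracellular(self, params):
        assert params.Ca_o == 1.8
        assert params.K_o == 5.4
        assert params.Na_o == 151.0

    def test_optimum_vs_seed_box(self, params, baseline_params):
        """10 of the 12 optimized values lie inside the +/-20% box around
        their baselines; the published Na+/Ca2+-exchanger maximum (65.5% of
        its printed original) and SERCA half-saturation (127.7%) are the
        known exceptions."""
        exceptions = {"I_NaCa_max": 3917.0463 / 5978.0,
                      "K_up": 3.1928e-4 / 2.5e-4}
        for name in OPTIMIZED_PARAMETER_NAMES:
            ratio = params.get(name) / baseline_params.get(name)
            if name in exceptions:
                assert ratio == pytest.approx(exceptions[name], rel=1e-9)
            else:
                assert 0.8 - 1e-12 <= ratio <= 1.2 + 1e-12, name

    def test_registry_covers_conductances(self, params):
        for name in CONDUCTANCE_REGISTRY:
            assert np.isfinite(params.get(name))

    def test_unknown_name(self, params):
        with pytest.raises(KeyError):
            params.get("G_nonsense")

    def test_roundtrip_is_value_exact(self, params, tmp_path):
        path = tmp_path / "p.yaml"
        save_parameters(params, path)
        again = load_parameters(path)
        for name in CONDUCTANCE_REGISTRY + OPTIMIZED_PARAMETER_NAMES:
            assert again.get(name) == params.get(name), name

    def test_partial_file_overlays_base(self, params, tmp_path):
        path = tmp_path / "overlay.yaml"
        path.write_text("base: paci2018-optimized\n"
                        "parameters: {G_Na: 1000.0}\n")
        p = load_parameters(path)
        assert p.G_Na == 1000.0
        assert p.with_values(G_Na=params.G_Na).ryr == params.ryr

    def test_empty_overlay_is_identity(self, params, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("base: paci2018-optimized\nparameters: {}\n")
        p = load_parameters(path)
        assert p.with_values() == params.with_values(
        ) or p.ryr == params.ryr  # name differs; physical content identical
        for name in CONDUCTANCE_REGISTRY:
            assert p.get(name) == params.get(name)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("parameters: {G_banana: 1.0}\n")
        with pytest.raises(KeyError, match="G_banana"):
            load_parameters(path)

    def test_missing_source(self):
        with pytest.raises(FileNotFoundError):
            load_parameters("no-such-set")


class TestTraceIO:
    @pytest.fixture()
    def short_trace(self, params):
        from hipsccm.simulate import packaged_steady_state
        y0 = packaged_steady_state("spontaneous")
        return hp.simulate(params, SPONTANEOUS, y0, 0.05, dt_out=1e-3)

    def test_roundtrip(self, short_trace, tmp_path, params):
        path = write_trace(tmp_path / "tr.csv", short_trace)
        back = read_trace(path, params=params)
        np.testing.assert_allclose(back.t, short_trace.t, rtol=0, atol=1e-12)
        np.testing.assert_allclose(back.states, short_trace.states,
                                   rtol=1e-12)
        assert back.protocol == short_trace.protocol
        assert back.solver["rtol"] == short_trace.solver["rtol"]

    def test_shuffled_columns(self, short_trace, tmp_path):
        import pandas as pd

        path = write_trace(tmp_path / "tr.csv", short_trace)
        df = pd.read_csv(path, skiprows=1)
        df = df[list(df.columns[::-1])]
        shuffled = tmp_path / "shuffled.csv"
        df.to_csv(shuffled, index=False)
        back = read_trace(shuffled)
        np.testing.assert_allclose(back.states, short_trace.states,
                                   rtol=1e-12)

    def test_missing_time_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Vm,Ca_i\n1,2\n")
        with pytest.raises(ValueError, match="'t'"):
            read_trace(path)

    def test_external_vm_only_table(self, tmp_path):
        """A bare time/Vm table (e.g. an experimental recording) still
        yields a usable trace for AP biomarkers."""
        import pandas as pd

        from hipsccm.fixtures import WaveformSpec, generate

        spec = WaveformSpec(family="rectangular", baseline=-75.0,
                            amplitude=100.0, plateau=0.3, period=1.0,
                            count=5)
        fx = generate(spec, kind="ap")
        pd.DataFrame({"t": fx.t, "Vm": fx.Vm}).to_csv(
            tmp_path / "vm.csv", index=False)
        tr = read_trace(tmp_path / "vm.csv")
        ap = hp.ap_biomarkers(tr)
        assert ap.CL == pytest.approx(1000.0, abs=0.5)


class TestRunConfig:
    def test_defaults(self):
        cfg = load_run_config({})
        assert cfg.params == "paci2018-optimized"
        assert cfg.protocol().mode == "spontaneous"

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="pacing_rte"):
            load_run_config({"pacing_rte": 2.0})

    def test_paced_protocol(self):
        cfg = load_run_config({"mode": "paced", "pacing_rate": 2.0})
        assert cfg.protocol().pacing_rate == 2.0
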