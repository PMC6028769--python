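"""Unit tests for the RyR release subsystem and the ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hipsccm as hp
from hipsccm import model
from hipsccm.parameters import RyRParameters
from hipsccm.simulate import SPONTANEOUS, prerun


class TestRyRCaSRModulation:
    def test_midpoint(self):
        assert model.ryr_casr_modulation(0.3) == pytest.approx(0.5)

    def test_saturation(self):
        assert model.ryr_casr_modulation(10.0) == pytest.approx(1.0, abs=1e-10)

    def test_empty_sr(self):
        # direct evaluation of the sigmoid at Ca_SR = 0
        expected = 1.0 - 1.0 / (1.0 + math.exp(-3.0))
        assert model.ryr_casr_modulation(0.0) == pytest.approx(expected,
                                                               rel=1e-12)
        assert expected == pytest.approx(0.04743, abs=5e-6)

    def test_strictly_increasing_and_bounded(self):
        grid = np.linspace(0.0, 2.0, 201)
        vals = model.ryr_casr_modulation(grid)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))

    def test_negative_domain_error(self):
        with pytest.raises(ValueError):
            model.ryr_casr_modulation(-0.1)


class TestRyRGateSteadyStates:
    def setup_method(self):
        self.ryr = RyRParameters()

    def test_open_gate_midpoint(self):
        # Ca_i (uM) equal to RyR_a + o_half puts the open gate at 1/2
        RyR_a = 0.03
        ca_mM = (RyR_a + self.ryr.o_half) / 1e3
        _, o_ss, _ = model.ryr_gate_steady_states(ca_mM, RyR_a, self.ryr)
        assert o_ss == pytest.approx(0.5, rel=1e-12)

    def test_closed_gate_midpoint(self):
        RyR_a = 0.03
        ca_mM = (RyR_a + self.ryr.c_half) / 1e3
        _, _, c_ss = model.ryr_gate_steady_states(ca_mM, RyR_a, self.ryr)
        assert c_ss == pytest.approx(0.5, rel=1e-12)

    def test_adaptation_limit_is_a1(self):
        a_ss, _, _ = model.ryr_gate_steady_states(10.0, 0.03, self.ryr)
        assert a_ss == pytest.approx(self.ryr.a1, rel=1e-9)

    def test_monotonicity_in_cai(self):
        # strict monotonicity on the unsaturated range around the
        # half-activations (floats saturate the sigmoids further out)
        ca = np.linspace(1e-6, 8e-5, 300)
        with np.errstate(over="ignore"):
            a, o, c = model.ryr_gate_steady_states(ca, 0.03, self.ryr)
        assert np.all(np.diff(a) > 0)
        assert np.all(np.diff(o) > 0)
        assert np.all(np.diff(c) < 0)
        assert np.all((o >= 0) & (o <= 1) & (c >= 0) & (c <= 1))

    def test_negative_cai_rejected(self):
        with pytest.raises(ValueError):
            model.ryr_gate_steady_states(-1e-4, 0.03, self.ryr)


class TestComputeIrel:
    def test_zero_gradient(self):
        y = model.default_initial_state()
        y[1] = y[2] = 0.2
        assert model.compute_irel(y, RyRParameters()) == 0.0

    def test_closed_channel(self):
        y = model.default_initial_state()
        y[21] = 0.0
        assert model.compute_irel(y, RyRParameters()) == 0.0

    def test_product_of_factors(self):
        # I_rel_max=62.5434, RyR_CaSR=0.5 (Ca_SR=0.3), RyR_o=0.1, RyR_c=1,
        # gradient 0.2 mM -> 0.62543 mM/s
        y = np.zeros(model.NSTATES)
        y[1] = 0.3
        y[2] = 0.1
        y[21] = 0.1
        y[22] = 1.0
        irel = model.compute_irel(y, RyRParameters())
        assert irel == pytest.approx(62.5434 * 0.5 * 0.1 * 1.0 * 0.2,
                                     rel=1e-12)

    @given(st.floats(0.05, 10.0), st.floats(1e-6, 2e-3),
           st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_release_direction(self, ca_sr, ca_i, o, c):
        y = np.zeros(model.NSTATES)
        y[1], y[2], y[21], y[22] = ca_sr, ca_i, o, c
        irel = model.compute_irel(y, RyRParameters())
        assert np.sign(irel) == np.sign(ca_sr - ca_i) or irel == 0.0


class TestApplyBlock:
    def test_identity(self, params):
        assert hp.apply_block(params, {}) == params

    def test_gna_scaled(self, params):
        blocked = hp.apply_block(params, {"G_Na": 0.18})
        assert blocked.G_Na == pytest.approx(0.18 * params.G_Na, rel=1e-15)
        # everything else untouched
        assert blocked.with_values(G_Na=params.G_Na) == params

    def test_gf_41pct_block(self, params):
        blocked = hp.apply_block(params, {"G_f": 0.59})
        assert blocked.G_f == pytest.approx(params.G_f * 0.59, rel=1e-15)

    def test_unknown_name_lists_registry(self, params):
        with pytest.raises(KeyError, match="G_Kr"):
            hp.apply_block(params, {"G_bogus": 0.5})

    def test_fraction_out_of_range(self, params):
        with pytest.raises(ValueError):
            hp.apply_block(params, {"G_Na": 1.5})


class TestImmatureRyR:
    def test_edit_values(self, params):
        imm = hp.make_immature_ryr(params)
        assert imm.ryr.o_half == pytest.approx(params.ryr.o_half - 0.002)
        assert imm.ryr.c_half == pytest.approx(params.ryr.c_half + 0.002)
        assert imm.ryr.tau_o == pytest.approx(params.ryr.tau_o * 2)
        assert imm.ryr.tau_c == pytest.approx(params.ryr.tau_c * 0.5)

    def test_involution(self, params):
        imm = hp.make_immature_ryr(params)
        back = imm.with_values(
            RyR_o_half=imm.ryr.o_half + 0.002,
            RyR_c_half=imm.ryr.c_half - 0.002,
            tau_RyR_o=imm.ryr.tau_o / 2,
            tau_RyR_c=imm.ryr.tau_c * 2)
        # taus invert exactly (power-of-two factors); the additive half
        # shifts invert to float round-off
        assert back.ryr.tau_o == params.ryr.tau_o
        assert back.ryr.tau_c == params.ryr.tau_c
        assert back.ryr.o_half == pytest.approx(params.ryr.o_half,
                                                rel=1e-12)
        assert back.ryr.c_half == pytest.approx(params.ryr.c_half,
                                                rel=1e-12)


class TestRHS:
    def test_state_dimension(self, params):
        y0 = model.default_initial_state()
        dy = model.rhs(0.0, y0, params)
        assert dy.shape == (23,)
        assert model.NSTATES == 23

    def test_nan_state_names_variable(self, params):
        y0 = model.default_initial_state()
        y0[5] = np.nan
        with pytest.raises(ValueError, match="f1"):
            model.rhs(0.0, y0, params)

    def test_gate_at_steady_state_has_zero_derivative(self, params):
        """Relaxation form: set the RyR gates to their steady state at fixed
        (Vm, Ca_i) and their derivatives vanish."""
        y = model.default_initial_state()
        a, o, c = model.ryr_gate_steady_states(y[2], y[20], params.ryr)
        y[20] = a
        # recompute o/c steady states against the adapted working point
        _, o, c = model.ryr_gate_steady_states(y[2], a, params.ryr)
        y[21], y[22] = o, c
        dy = model.rhs(0.0, y, params)
        assert abs(dy[20]) < 1e-12
        assert abs(dy[21]) < 1e-9
        assert abs(dy[22]) < 1e-9

    def test_isolated_sr_compartment(self, params):
        """With SERCA, leak and release all zero, SR Ca2+ is frozen."""
        p = params.with_values(V_max_up=0.0, I_leak_max=0.0, I_rel_max=0.0)
        y = model.default_initial_state()
        dy = model.rhs(0.0, y, p)
        assert dy[1] == 0.0

    def test_linear_gate_exponential_relaxation_oracle(self, params):
        """The Xf gate at clamped Vm follows x(t) = x_inf + (x0-x_inf)e^(-t/tau);
        the finite difference of the closed form matches the RHS."""
        y = model.default_initial_state()
        v = y[0] * 1e3
        xf_inf = 1.0 / (1.0 + math.exp((v + 77.85) / 5.0))
        tau = 1900.0 / (1.0 + math.exp((v + 15.0) / 10.0)) / 1000.0
        x0 = 0.3
        y[14] = x0
        dy = model.rhs(0.0, y, params)
        t = 1e-6
        x_t = xf_inf + (x0 - xf_inf) * math.exp(-t / tau)
        fd = (x_t - x0) / t
        assert dy[14] == pytest.approx(fd, rel=1e-4)
        assert dy[14] == pytest.approx((xf_inf - x0) / tau, rel=1e-8)

    def test_numba_and_python_kernels_agree(self, params):
        y = model.default_initial_state()
        p = model.pack_parameters(params, stim=3.0)
        a = model._rhs_py(0.0, y, p)
        b = model.rhs_core(0.0, y, p)
        np.testing.assert_allclose(a, b, rtol=1e-13)
        ca = model._currents_py(y, p)
        cb = model.currents_core(y, p)
        np.testing.assert_allclose(ca, cb, rtol=1e-13)

    def test_quiescence_at_potassium_nernst(self, params):
        """With all non-K+ sarcolemmal currents zeroed and Vm at E_K, the
        membrane stays at the K+ Nernst potential (drift < 1 mV over 10 s)."""
        p = params.with_values(**{n: 0.0 for n in
                                  ("G_Na", "G_NaL", "G_CaL", "G_f", "G_bNa",
                                   "G_bCa", "G_pCa", "I_NaCa_max",
                                   "I_NaK_max")})
        R, T, F = 8.314472, 310.0, 96485.3415
        e_k = R * T / F * math.log(p.K_o / p.K_i)
        y = model.default_initial_state()
        y[0] = e_k
        y_end = prerun(p, SPONTANEOUS, y, 10.0)
        assert abs(y_end[0] - e_k) * 1e3 < 1.0

    def test_membrane_current_balance_at_fixed_point(self, params):
        """At a quiescent fixed point the membrane currents sum to zero."""
        p = params.with_values(G_f=0.0, G_Na=0.0, G_NaL=0.0, G_CaL=0.0)
        y = prerun(p, SPONTANEOUS, model.default_initial_state(), 50.0)
        dy = model.rhs(0.0, y, p)
        # dVm/dt equals minus the current sum; quiescent -> ~0 (V/s)
        assert abs(dy[0]) < 5e-4
        cur = model.compute_currents(y, p)
        total = sum(cur[k] for k in
                    ("I_Na", "I_NaL", "I_CaL", "I_f", "I_to", "I_Kr", "I_Ks",
                     "I_K1", "I_NaK", "I_NaCa", "I_pCa", "I_bNa", "I_bCa"))
        assert total == pytest.approx(-dy[0], abs=1e-12)
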