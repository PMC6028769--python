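"""State layout, ionic currents and the ODE right-hand side.

The model has 23 state variables: membrane potential, 16 Hodgkin-Huxley-type
gates (including the legacy SR-release inactivation gate ``g``, retained from
the predecessor model but decoupled from the new release flux), the three
ryanodine-receptor gates, and the Na+, cytosolic Ca2+ and SR Ca2+
concentrations.  Intracellular K+ is held constant.

The right-hand side is written in scalar NumPy so that it can be JIT-compiled
with numba when available; the pure-Python function is kept as a fallback and
exercised by the test suite.

Membrane currents are expressed as densities (A/F); the membrane equation is

    dVm/dt = -(I_K1 + I_to + I_Kr + I_Ks + I_CaL + I_NaK + I_Na + I_NaL
               + I_NaCa + I_pCa + I_f + I_bNa + I_bCa - I_stim)

SR release follows the three-gate ryanodine-receptor formulation

    I_rel = I_rel_max * RyR_CaSR(Ca_SR) * RyR_o * RyR_c * (Ca_SR - Ca_i)

with sigmoidal gate steady states driven by cytosolic Ca2+ and an adaptation
gate RyR_a that shifts the open/closed half-activations.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ModelParameters, RyRParameters

__all__ = [
    "STATE_NAMES", "NSTATES", "CURRENT_NAMES",
    "pack_parameters", "rhs", "compute_currents", "compute_currents_trace",
    "ryr_casr_modulation", "ryr_gate_steady_states", "compute_irel",
    "default_initial_state",
]

STATE_NAMES: tuple[str, ...] = (
    "Vm", "Ca_SR", "Ca_i", "g", "d", "f1", "f2", "fCa",
    "Xr1", "Xr2", "Xs", "h", "j", "m", "Xf", "q", "r",
    "Na_i", "mL", "hL", "RyR_a", "RyR_o", "RyR_c",
)
NSTATES = len(STATE_NAMES)

CURRENT_NAMES: tuple[str, ...] = (
    "I_Na", "I_NaL", "I_CaL", "I_f", "I_to", "I_Kr", "I_Ks", "I_K1",
    "I_NaK", "I_NaCa", "I_pCa", "I_bNa", "I_bCa",
    "I_rel", "I_up", "I_leak",
)

# physical constants
_F = 96485.3415   # C/mol
_R = 8.314472     # J/(mol K)
_T = 310.0        # K

# parameter-vector slots
NPARAMS = 37
(_G_NA, _G_CAL, _G_KR, _G_KS, _G_K1, _G_F, _G_TO, _G_NAL, _G_BNA, _G_BCA,
 _G_PCA, _KNACA, _PNAK, _VMAXUP, _KUP, _VLEAK, _ALPHA, _IRELMAX,
 _RYR_A1, _RYR_A2, _RYR_AHALF, _RYR_OHALF, _RYR_CHALF,
 _RYR_AK, _RYR_OK, _RYR_CK, _TAU_A, _TAU_O, _TAU_C,
 _NAO, _KO, _CAO, _KI, _CM, _VC, _VSR, _STIM) = range(NPARAMS)


def pack_parameters(params: ModelParameters, stim: float = 0.0) -> np.ndarray:
    """Flatten a parameter set into the vector consumed by the ODE core.

    ``stim`` is the stimulus current density (A/F) held in the last slot; the
    simulation engine rewrites it per pacing segment.
    """
    r = params.ryr
    p = np.array([
        params.G_Na, params.G_CaL, params.G_Kr, params.G_Ks, params.G_K1,
        params.G_f, params.G_to, params.G_NaL, params.G_bNa, params.G_bCa,
        params.G_pCa, params.I_NaCa_max, params.I_NaK_max, params.V_max_up,
        params.K_up, params.I_leak_max, params.alpha, r.I_rel_max,
        r.a1, r.a2, r.a_half, r.o_half, r.c_half, r.a_k, r.o_k, r.c_k,
        r.tau_a, r.tau_o, r.tau_c,
        params.Na_o, params.K_o, params.Ca_o, params.K_i,
        params.Cm, params.V_c, params.V_SR, stim,
    ], dtype=np.float64)
    return p


def _rhs_py(t, y, p):  # noqa: C901  (single flat kernel, deliberately)
    dY = np.zeros(NSTATES)

    Vm = y[0]
    Ca_SR = y[1]
    Cai = y[2]
    g_gate = y[3]
    d = y[4]
    f1 = y[5]
    f2 = y[6]
    fCa = y[7]
    Xr1 = y[8]
    Xr2 = y[9]
    Xs = y[10]
    h = y[11]
    j = y[12]
    m = y[13]
    Xf = y[14]
    q = y[15]
    r = y[16]
    Nai = y[17]
    mL = y[18]
    hL = y[19]
    RyRa = y[20]
    RyRo = y[21]
    RyRc = y[22]

    Nao = p[_NAO]
    Ko = p[_KO]
    Cao = p[_CAO]
    Ki = p[_KI]
    v = Vm * 1000.0  # mV, for the gate fits

    RTF = _R * _T / _F
    E_Na = RTF * math.log(Nao / Nai)
    E_Ca = 0.5 * RTF * math.log(Cao / Cai)
    E_K = RTF * math.log(Ko / Ki)
    PkNa = 0.03
    E_Ks = RTF * math.log((Ko + PkNa * Nao) / (Ki + PkNa * Nai))

    # --- fast Na+ current
    i_Na = p[_G_NA] * m ** 3 * h * j * (Vm - E_Na)

    h_inf = 1.0 / math.sqrt(1.0 + math.exp((v + 72.1) / 5.7))
    alpha_h = 0.057 * math.exp(-(v + 80.0) / 6.8)
    beta_h = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    if Vm < -0.0385:
        tau_h = 1.5 / ((alpha_h + beta_h) * 1000.0)
    else:
        tau_h = 1.5 * 1.6947 / 1000.0
    dY[11] = (h_inf - h) / tau_h

    j_inf = 1.0 / math.sqrt(1.0 + math.exp((v + 72.1) / 5.7))
    if Vm < -0.04:
        alpha_j = (-25428.0 * math.exp(0.2444 * v)
                   - 6.948e-6 * math.exp(-0.04391 * v)) * (v + 37.78) / (
                       1.0 + math.exp(0.311 * (v + 79.23)))
        beta_j = 0.02424 * math.exp(-0.01052 * v) / (
            1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        alpha_j = 0.0
        beta_j = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    tau_j = 7.0 / ((alpha_j + beta_j) * 1000.0)
    dY[12] = (j_inf - j) / tau_j

    m_inf = (1.0 + math.exp((-v - 34.1) / 5.9)) ** (-1.0 / 3.0)
    alpha_m = 1.0 / (1.0 + math.exp((-v - 60.0) / 5.0))
    beta_m = (0.1 / (1.0 + math.exp((v + 35.0) / 5.0))
              + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0)))
    tau_m = alpha_m * beta_m / 1000.0
    dY[13] = (m_inf - m) / tau_m

    # --- late Na+ current
    i_NaL = p[_G_NAL] * mL ** 3 * hL * (Vm - E_Na)
    mL_inf = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    alpha_mL = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    beta_mL = (0.1 / (1.0 + math.exp((v + 35.0) / 5.0))
               + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0)))
    tau_mL = alpha_mL * beta_mL / 1000.0
    dY[18] = (mL_inf - mL) / tau_mL
    hL_inf = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    tau_hL = 0.200
    dY[19] = (hL_inf - hL) / tau_hL

    # --- funny current
    E_f = -0.017
    i_f = p[_G_F] * Xf * (Vm - E_f)
    i_fNa = 0.42 * p[_G_F] * Xf * (Vm - E_Na)
    Xf_inf = 1.0 / (1.0 + math.exp((v + 77.85) / 5.0))
    tau_Xf = 1900.0 / (1.0 + math.exp((v + 15.0) / 10.0)) / 1000.0
    dY[14] = (Xf_inf - Xf) / tau_Xf

    # --- L-type Ca2+ current (GHK-like driving term)
    ex = math.exp(2.0 * Vm * _F / (_R * _T))
    if abs(Vm) > 1e-9:
        drive = (4.0 * Vm * _F * _F / (_R * _T)
                 * (Cai * ex - 0.341 * Cao) / (ex - 1.0))
    else:
        drive = 2.0 * _F * (Cai - 0.341 * Cao)
    i_CaL = p[_G_CAL] * drive * d * f1 * f2 * fCa

    d_inf = 1.0 / (1.0 + math.exp(-(v + 9.1) / 7.0))
    alpha_d = 0.25 + 1.4 / (1.0 + math.exp((-v - 35.0) / 13.0))
    beta_d = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gamma_d = 1.0 / (1.0 + math.exp((-v + 50.0) / 20.0))
    tau_d = (alpha_d * beta_d + gamma_d) / 1000.0
    dY[4] = (d_inf - d) / tau_d

    f1_inf = 1.0 / (1.0 + math.exp((v + 26.0) / 3.0))
    if f1_inf - f1 > 0.0:
        constf1 = 1.0 + 1433.0 * (Cai - 50.0e-6)
    else:
        constf1 = 1.0
    tau_f1 = (20.0 + 1102.5 * math.exp(-(((v + 27.0) ** 2) / 15.0) ** 2)
              + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
              + 180.0 / (1.0 + math.exp((30.0 + v) / 10.0))) * constf1 / 1000.0
    dY[5] = (f1_inf - f1) / tau_f1

    f2_inf = 0.33 + 0.67 / (1.0 + math.exp((v + 32.0) / 4.0))
    tau_f2 = (600.0 * math.exp(-((v + 25.0) ** 2) / 170.0)
              + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
              + 16.0 / (1.0 + math.exp((30.0 + v) / 10.0))) / 1000.0
    dY[6] = (f2_inf - f2) / tau_f2

    alpha_fCa = 1.0 / (1.0 + (Cai / 0.0006) ** 8)
    beta_fCa = 0.1 / (1.0 + math.exp((Cai - 0.0009) / 0.0001))
    gamma_fCa = 0.3 / (1.0 + math.exp((Cai - 0.00075) / 0.0008))
    fCa_inf = (alpha_fCa + beta_fCa + gamma_fCa) / 1.3156
    if Vm > -0.06 and fCa_inf > fCa:
        constfCa = 0.0
    else:
        constfCa = 1.0
    dY[7] = constfCa * (fCa_inf - fCa) / 0.002

    # --- transient outward K+
    i_to = p[_G_TO] * (Vm - E_K) * q * r
    q_inf = 1.0 / (1.0 + math.exp((v + 53.0) / 13.0))
    tau_q = (6.06 + 39.102 / (0.57 * math.exp(-0.08 * (v + 44.0))
                              + 0.065 * math.exp(0.1 * (v + 45.93)))) / 1000.0
    dY[15] = (q_inf - q) / tau_q
    r_inf = 1.0 / (1.0 + math.exp(-(v - 22.3) / 18.75))
    tau_r = (2.75352 + 14.40516 / (1.037 * math.exp(0.09 * (v + 30.61))
                                   + 0.369 * math.exp(-0.12 * (v + 23.84)))) / 1000.0
    dY[16] = (r_inf - r) / tau_r

    # --- slow delayed rectifier
    i_Ks = (p[_G_KS] * (Vm - E_Ks) * Xs ** 2
            * (1.0 + 0.6 / (1.0 + (3.8e-5 / Cai) ** 1.4)))
    Xs_inf = 1.0 / (1.0 + math.exp((-v - 20.0) / 16.0))
    alpha_Xs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - v) / 6.0))
    beta_Xs = 1.0 / (1.0 + math.exp((-60.0 + v) / 20.0))
    dY[10] = (Xs_inf - Xs) / (alpha_Xs * beta_Xs / 1000.0)

    # --- rapid delayed rectifier
    i_Kr = p[_G_KR] * (Vm - E_K) * Xr1 * Xr2 * math.sqrt(Ko / 5.4)
    L0 = 0.025
    Q = 2.3
    V_half = 1000.0 * (-_R * _T / (_F * Q)
                       * math.log((1.0 + Cao / 2.6) ** 4
                                  / (L0 * (1.0 + Cao / 0.58) ** 4)) - 0.019)
    Xr1_inf = 1.0 / (1.0 + math.exp((V_half - v) / 4.9))
    alpha_Xr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    beta_Xr1 = 6.0 / (1.0 + math.exp((30.0 + v) / 11.5))
    dY[8] = (Xr1_inf - Xr1) / (alpha_Xr1 * beta_Xr1 / 1000.0)
    Xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 50.0))
    alpha_Xr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    beta_Xr2 = 1.12 / (1.0 + math.exp((-60.0 + v) / 20.0))
    dY[9] = (Xr2_inf - Xr2) / (alpha_Xr2 * beta_Xr2 / 1000.0)

    # --- inward rectifier (instantaneous gate)
    vEK = v - E_K * 1000.0
    alpha_K1 = 3.91 / (1.0 + math.exp(0.5942 * (vEK - 200.0)))
    beta_K1 = (-1.509 * math.exp(0.0002 * (vEK + 100.0))
               + math.exp(0.5886 * (vEK - 10.0))) / (
                   1.0 + math.exp(0.4547 * vEK))
    XK1_inf = alpha_K1 / (alpha_K1 + beta_K1)
    i_K1 = p[_G_K1] * XK1_inf * (Vm - E_K) * math.sqrt(Ko / 5.4)

    # --- Na+/Ca2+ exchanger
    KmCa = 1.38
    KmNai = 87.5
    Ksat = 0.1
    gam = 0.35
    efp = math.exp(gam * Vm * _F / (_R * _T))
    efm = math.exp((gam - 1.0) * Vm * _F / (_R * _T))
    i_NaCa = (p[_KNACA]
              * (efp * Nai ** 3 * Cao - efm * Nao ** 3 * Cai * p[_ALPHA])
              / ((KmNai ** 3 + Nao ** 3) * (KmCa + Cao)
                 * (1.0 + Ksat * efm)))

    # --- Na+/K+ pump
    i_NaK = (p[_PNAK] * Ko / (Ko + 1.0) * Nai / (Nai + 40.0)
             / (1.0 + 0.1245 * math.exp(-0.1 * Vm * _F / (_R * _T))
                + 0.0353 * math.exp(-Vm * _F / (_R * _T))))

    # --- sarcolemmal Ca2+ pump and backgrounds
    i_pCa = p[_G_PCA] * Cai / (Cai + 0.0005)
    i_bNa = p[_G_BNA] * (Vm - E_Na)
    i_bCa = p[_G_BCA] * (Vm - E_Ca)

    # --- SR fluxes
    i_up = p[_VMAXUP] / (1.0 + p[_KUP] ** 2 / Cai ** 2)
    i_leak = (Ca_SR - Cai) * p[_VLEAK]

    ryr_casr = 1.0 - 1.0 / (1.0 + math.exp((Ca_SR - 0.3) / 0.1))
    i_rel = p[_IRELMAX] * ryr_casr * RyRo * RyRc * (Ca_SR - Cai)

    ca_uM = 1000.0 * Cai
    RyRa_inf = p[_RYR_A1] - p[_RYR_A2] / (
        1.0 + math.exp((ca_uM - p[_RYR_AHALF]) / p[_RYR_AK]))
    dY[20] = (RyRa_inf - RyRa) / p[_TAU_A]
    RyRo_inf = 1.0 - 1.0 / (
        1.0 + math.exp((ca_uM - (RyRa + p[_RYR_OHALF])) / p[_RYR_OK]))
    dY[21] = (RyRo_inf - RyRo) / p[_TAU_O]
    RyRc_inf = 1.0 / (
        1.0 + math.exp((ca_uM - (RyRa + p[_RYR_CHALF])) / p[_RYR_CK]))
    dY[22] = (RyRc_inf - RyRc) / p[_TAU_C]

    # legacy release-inactivation gate (decoupled from I_rel)
    if Cai <= 0.00035:
        g_inf = 1.0 / (1.0 + (Cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (Cai / 0.00035) ** 16)
    if Vm > -0.06 and g_inf > g_gate:
        const_g = 0.0
    else:
        const_g = 1.0
    dY[3] = const_g * (g_inf - g_gate) / 0.002

    # --- Ca2+ buffering (rapid-buffer approximation) and balances
    Buf_C = 0.25
    Buf_SR = 10.0
    Kbuf_C = 0.001
    Kbuf_SR = 0.3
    bufc = 1.0 / (1.0 + Buf_C * Kbuf_C / (Cai + Kbuf_C) ** 2)
    bufsr = 1.0 / (1.0 + Buf_SR * Kbuf_SR / (Ca_SR + Kbuf_SR) ** 2)

    Cm = p[_CM]
    Vc = p[_VC]
    Vsr = p[_VSR]
    dY[2] = bufc * (i_leak - i_up + i_rel
                    - (i_CaL + i_bCa + i_pCa - 2.0 * i_NaCa)
                    * Cm / (2.0 * Vc * _F * 1.0e-18))
    dY[1] = bufsr * Vc / Vsr * (i_up - (i_rel + i_leak))

    dY[17] = -Cm * (i_Na + i_NaL + i_bNa + 3.0 * i_NaK + 3.0 * i_NaCa
                    + i_fNa) / (_F * Vc * 1.0e-18)

    i_stim = p[_STIM]
    dY[0] = -(i_K1 + i_to + i_Kr + i_Ks + i_CaL + i_NaK + i_Na + i_NaL
              + i_NaCa + i_pCa + i_f + i_bNa + i_bCa - i_stim)
    return dY


def _currents_py(y, p):
    """All membrane currents (A/F) and SR fluxes (mM/s) at one state."""
    out = np.empty(len(CURRENT_NAMES))
    Vm = y[0]
    Ca_SR = y[1]
    Cai = y[2]
    d = y[4]
    f1 = y[5]
    f2 = y[6]
    fCa = y[7]
    Xr1 = y[8]
    Xr2 = y[9]
    Xs = y[10]
    h = y[11]
    j = y[12]
    m = y[13]
    Xf = y[14]
    q = y[15]
    r = y[16]
    Nai = y[17]
    mL = y[18]
    hL = y[19]
    RyRo = y[21]
    RyRc = y[22]

    Nao = p[_NAO]
    Ko = p[_KO]
    Cao = p[_CAO]
    Ki = p[_KI]
    v = Vm * 1000.0
    RTF = _R * _T / _F
    E_Na = RTF * math.log(Nao / Nai)
    E_Ca = 0.5 * RTF * math.log(Cao / Cai)
    E_K = RTF * math.log(Ko / Ki)
    E_Ks = RTF * math.log((Ko + 0.03 * Nao) / (Ki + 0.03 * Nai))

    out[0] = p[_G_NA] * m ** 3 * h * j * (Vm - E_Na)
    out[1] = p[_G_NAL] * mL ** 3 * hL * (Vm - E_Na)

    ex = math.exp(2.0 * Vm * _F / (_R * _T))
    if abs(Vm) > 1e-9:
        drive = (4.0 * Vm * _F * _F / (_R * _T)
                 * (Cai * ex - 0.341 * Cao) / (ex - 1.0))
    else:
        drive = 2.0 * _F * (Cai - 0.341 * Cao)
    out[2] = p[_G_CAL] * drive * d * f1 * f2 * fCa

    out[3] = p[_G_F] * Xf * (Vm - (-0.017))
    out[4] = p[_G_TO] * (Vm - E_K) * q * r
    out[5] = p[_G_KR] * (Vm - E_K) * Xr1 * Xr2 * math.sqrt(Ko / 5.4)
    out[6] = (p[_G_KS] * (Vm - E_Ks) * Xs ** 2
              * (1.0 + 0.6 / (1.0 + (3.8e-5 / Cai) ** 1.4)))

    vEK = v - E_K * 1000.0
    alpha_K1 = 3.91 / (1.0 + math.exp(0.5942 * (vEK - 200.0)))
    beta_K1 = (-1.509 * math.exp(0.0002 * (vEK + 100.0))
               + math.exp(0.5886 * (vEK - 10.0))) / (
                   1.0 + math.exp(0.4547 * vEK))
    out[7] = (p[_G_K1] * alpha_K1 / (alpha_K1 + beta_K1)
              * (Vm - E_K) * math.sqrt(Ko / 5.4))

    out[8] = (p[_PNAK] * Ko / (Ko + 1.0) * Nai / (Nai + 40.0)
              / (1.0 + 0.1245 * math.exp(-0.1 * Vm * _F / (_R * _T))
                 + 0.0353 * math.exp(-Vm * _F / (_R * _T))))

    efp = math.exp(0.35 * Vm * _F / (_R * _T))
    efm = math.exp(-0.65 * Vm * _F / (_R * _T))
    out[9] = (p[_KNACA]
              * (efp * Nai ** 3 * Cao - efm * Nao ** 3 * Cai * p[_ALPHA])
              / ((87.5 ** 3 + Nao ** 3) * (1.38 + Cao) * (1.0 + 0.1 * efm)))

    out[10] = p[_G_PCA] * Cai / (Cai + 0.0005)
    out[11] = p[_G_BNA] * (Vm - E_Na)
    out[12] = p[_G_BCA] * (Vm - E_Ca)

    ryr_casr = 1.0 - 1.0 / (1.0 + math.exp((Ca_SR - 0.3) / 0.1))
    out[13] = p[_IRELMAX] * ryr_casr * RyRo * RyRc * (Ca_SR - Cai)
    out[14] = p[_VMAXUP] / (1.0 + p[_KUP] ** 2 / Cai ** 2)
    out[15] = (Ca_SR - Cai) * p[_VLEAK]
    return out


# optional numba acceleration; the pure-Python kernels remain the reference
try:  # pragma: no cover - exercised indirectly
    import numba

    rhs_core = numba.njit(cache=True, fastmath=False)(_rhs_py)
    currents_core = numba.njit(cache=True, fastmath=False)(_currents_py)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    rhs_core = _rhs_py
    currents_core = _currents_py
    HAVE_NUMBA = False


def rhs(t: float, y: np.ndarray, params: ModelParameters,
        stimulus: float = 0.0) -> np.ndarray:
    """Time derivative of the 23-component state.

    ``stimulus`` is the instantaneous stimulus current density (A/F,
    depolarizing positive).  Raises ``ValueError`` naming the first offending
    state variable if the state contains NaN/Inf.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(y))[0])]
        raise ValueError(f"non-finite state variable: {bad}")
    return rhs_core(t, y, pack_parameters(params, stim=stimulus))


def compute_currents(y: np.ndarray, params: ModelParameters) -> dict[str, float]:
    """Membrane currents (A/F) and SR fluxes (mM/s) at a single state."""
    vals = currents_core(np.asarray(y, dtype=float), pack_parameters(params))
    return dict(zip(CURRENT_NAMES, vals))


def compute_currents_trace(states: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Currents for an (n, 23) array of states -> (n, ncurrents)."""
    p = pack_parameters(params)
    states = np.asarray(states, dtype=float)
    out = np.empty((states.shape[0], len(CURRENT_NAMES)))
    for i in range(states.shape[0]):
        out[i] = currents_core(states[i], p)
    return out


# -- RyR subsystem, exposed directly for testing and analysis ------------

def ryr_casr_modulation(Ca_SR: float) -> float:
    """Luminal-Ca2+ modulation of the release flux, sigmoid in Ca_SR (mM).

    Strictly increasing, bounded in (0, 1), midpoint at 0.3 mM.
    """
    Ca_SR = np.asarray(Ca_SR, dtype=float)
    if np.any(Ca_SR < 0):
        raise ValueError("Ca_SR must be >= 0")
    out = 1.0 - 1.0 / (1.0 + np.exp((Ca_SR - 0.3) / 0.1))
    return float(out) if out.ndim == 0 else out

def ryr_gate_steady_states(Ca_i: float, RyR_a: float,
                           ryr: RyRParameters) -> tuple[float, float, float]:
    """Steady states of the adaptation, open and closed RyR gates.

    ``Ca_i`` in mM (converted to uM internally), ``RyR_a`` the current
    adaptation-gate value (uM scale).  Returns ``(a_ss, o_ss, c_ss)``.
    """
    if np.any(np.asarray(Ca_i) < 0):
        raise ValueError("Ca_i must be >= 0")
    ca = 1000.0 * np.asarray(Ca_i, dtype=float)
    a_ss = ryr.a1 - ryr.a2 / (1.0 + np.exp((ca - ryr.a_half) / ryr.a_k))
    o_ss = 1.0 - 1.0 / (1.0 + np.exp((ca - (RyR_a + ryr.o_half)) / ryr.o_k))
    c_ss = 1.0 / (1.0 + np.exp((ca - (RyR_a + ryr.c_half)) / ryr.c_k))
    if np.ndim(a_ss) == 0:
        return float(a_ss), float(o_ss), float(c_ss)
    return a_ss, o_ss, c_ss


def compute_irel(state: np.ndarray, ryr: RyRParameters) -> float:
    """SR Ca2+ release flux (mM/s) at one state vector."""
    Ca_SR = state[1]
    Ca_i = state[2]
    RyRo = state[21]
    RyRc = state[22]
    return float(ryr.I_rel_max * ryr_casr_modulation(Ca_SR)
                 * RyRo * RyRc * (Ca_SR - Ca_i))


def default_initial_state() -> np.ndarray:
    """A generic depolarizable resting state used to seed long pre-runs."""
    y0 = np.zeros(NSTATES)
    y0[0] = -0.070   # Vm (V)
    y0[1] = 0.32     # Ca_SR (mM)
    y0[2] = 0.0002   # Ca_i (mM)
    y0[3] = 0.0      # legacy g gate
    y0[4] = 0.0      # d
    y0[5] = 1.0      # f1
    y0[6] = 1.0      # f2
    y0[7] = 1.0      # fCa
    y0[8] = 0.0      # Xr1
    y0[9] = 1.0      # Xr2
    y0[10] = 0.0     # Xs
    y0[11] = 0.75    # h
    y0[12] = 0.75    # j
    y0[13] = 0.0     # m
    y0[14] = 0.1     # Xf
    y0[15] = 1.0     # q
    y0[16] = 0.0     # r
    y0[17] = 9.2     # Na_i (mM)
    y0[18] = 0.0     # mL
    y0[19] = 0.75    # hL
    y0[20] = 0.3     # RyR_a
    y0[21] = 0.9     # RyR_o
    y0[22] = 0.1     # RyR_c
    return y0
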