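"""Human epicardial ventricular myocyte model (ten Tusscher-Panfilov 2006).

Full implementation of the 2006 ten Tusscher-Panfilov human ventricular
formulation with the epicardial parameter set: fast Na⁺ current, L-type
Ca²⁺ current with subspace Ca²⁺-dependent inactivation, transient outward,
rapid and slow delayed-rectifier and inward-rectifier K⁺ currents,
Na⁺/Ca²⁺ exchange, Na⁺/K⁺ pump, plateau and background currents, and
three-compartment Ca²⁺ dynamics (cytosol, dyadic subspace, SR) with a
four-state CICR release gate.  Intracellular Na⁺ and K⁺ are dynamic.

Paced at a 1000-ms cycle length the model produces the documented
epicardial AP: spike-and-dome morphology with APD90 near 300 ms.

Units: mV, ms, µA/µF, mM.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import MembraneModel

__all__ = ["build_human_model", "HUMAN_STATE_NAMES", "HUMAN_PARAM_NAMES",
           "HUMAN_CURRENT_NAMES"]

HUMAN_STATE_NAMES = (
    "V_m", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fCass", "Rbar", "Cai", "CaSS", "CaSR", "Nai", "Ki",
)

HUMAN_PARAM_NAMES = (
    "g_Na", "g_CaL", "g_to", "g_Kr", "g_Ks", "g_K1", "k_NCX", "p_NaK",
    "g_pCa", "g_pK", "g_bNa", "g_bCa",
)

HUMAN_CURRENT_NAMES = (
    "I_Na", "I_CaL", "I_to", "I_Kr", "I_Ks", "I_K1", "I_NCX", "I_NaK",
    "I_pCa", "I_pK", "I_bNa", "I_bCa",
)

_HUMAN_CONDUCTANCES = {
    "I_Na": "g_Na", "I_CaL": "g_CaL", "I_to": "g_to", "I_Kr": "g_Kr",
    "I_Ks": "g_Ks", "I_K1": "g_K1", "I_NCX": "k_NCX", "I_NaK": "p_NaK",
    "I_pCa": "g_pCa", "I_pK": "g_pK", "I_bNa": "g_bNa", "I_bCa": "g_bCa",
}

# epicardial parameter set
_HUMAN_DEFAULTS = {
    "g_Na": 14.838,
    "g_CaL": 3.98e-5,
    "g_to": 0.294,
    "g_Kr": 0.153,
    "g_Ks": 0.392,
    "g_K1": 5.405,
    "k_NCX": 1000.0,
    "p_NaK": 2.724,
    "g_pCa": 0.1238,
    "g_pK": 0.0146,
    "g_bNa": 2.9e-4,
    "g_bCa": 5.92e-4,
}

_RTONF = 8314.472 * 310.0 / 96485.3415
_F_RT = 1.0 / _RTONF
_KO = 5.4
_NAO = 140.0
_CAO = 2.0


@njit(cache=True)
def _human_currents_node(y, p, out):
    V = y[0]
    m, h, j = y[1], y[2], y[3]
    xr1, xr2, xs = y[4], y[5], y[6]
    r, s = y[7], y[8]
    d, f, f2, fcass = y[9], y[10], y[11], y[12]
    cai, cass = y[14], y[15]
    nai, ki = y[17], y[18]

    rtonf = 8314.472 * 310.0 / 96485.3415
    e_na = rtonf * math.log(140.0 / nai)
    e_k = rtonf * math.log(5.4 / ki)
    e_ks = rtonf * math.log((5.4 + 0.03 * 140.0) / (ki + 0.03 * nai))
    e_ca = 0.5 * rtonf * math.log(2.0 / max(cai, 1e-9))

    out[0] = p[0] * m * m * m * h * j * (V - e_na)                    # I_Na
    # L-type Ca current (GHK-like driving term measured from +15 mV)
    vshift = V - 15.0
    if abs(vshift) < 1e-6:
        vshift = 1e-6
    ex = math.exp(2.0 * vshift / rtonf)
    out[1] = (p[1] * d * f * f2 * fcass * 4.0 * vshift
              * (96485.3415 / rtonf)
              * (0.25 * cass * ex - 2.0) / (ex - 1.0))                # I_CaL
    out[2] = p[2] * r * s * (V - e_k)                                 # I_to
    out[3] = p[3] * math.sqrt(5.4 / 5.4) * xr1 * xr2 * (V - e_k)      # I_Kr
    out[4] = p[4] * xs * xs * (V - e_ks)                              # I_Ks
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - e_k - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (V - e_k + 100.0))
            + math.exp(0.1 * (V - e_k - 10.0)))
           / (1.0 + math.exp(-0.5 * (V - e_k))))
    out[5] = p[5] * (ak1 / (ak1 + bk1)) * (V - e_k)                   # I_K1
    ef = math.exp(0.35 * V / rtonf)
    er = math.exp(-0.65 * V / rtonf)
    num = ef * nai ** 3 * 2.0 - er * 140.0 ** 3 * cai * 2.5
    den = (87.5 ** 3 + 140.0 ** 3) * (1.38 + 2.0) * (1.0 + 0.1 * er)
    out[6] = p[6] * num / den                                         # I_NCX
    out[7] = (p[7] * 5.4 * nai / ((5.4 + 1.0) * (nai + 40.0))
              / (1.0 + 0.1245 * math.exp(-0.1 * V / rtonf)
                 + 0.0353 * math.exp(-V / rtonf)))                    # I_NaK
    out[8] = p[8] * cai / (cai + 0.0005)                              # I_pCa
    out[9] = p[9] * (V - e_k) / (1.0 + math.exp((25.0 - V) / 5.98))   # I_pK
    out[10] = p[10] * (V - e_na)                                      # I_bNa
    out[11] = p[11] * (V - e_ca)                                      # I_bCa


@njit(cache=True)
def _human_step_all(Y, p, dt, istim):
    """One Rush-Larsen/Euler step for every node of Y (n_nodes, 19)."""
    n = Y.shape[0]
    cur = np.empty(12)
    rtonf = 8314.472 * 310.0 / 96485.3415
    for k in range(n):
        y = Y[k]
        V = y[0]

        # --- I_Na gates ---------------------------------------------------
        m_inf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
        am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
        bm = (0.1 / (1.0 + math.exp((V + 35.0) / 5.0))
              + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0)))
        tau_m = am * bm
        h_inf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
        if V >= -40.0:
            ah = 0.0
            bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        else:
            ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
            bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
        tau_h = 1.0 / (ah + bh)
        j_inf = h_inf
        if V >= -40.0:
            aj = 0.0
            bj = (0.6 * math.exp(0.057 * V)
                  / (1.0 + math.exp(-0.1 * (V + 32.0))))
        else:
            aj = ((-2.5428e4 * math.exp(0.2444 * V)
                   - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
                  / (1.0 + math.exp(0.311 * (V + 79.23))))
            bj = (0.02424 * math.exp(-0.01052 * V)
                  / (1.0 + math.exp(-0.1378 * (V + 40.14))))
        tau_j = 1.0 / (aj + bj)

        # --- I_Kr gates ---------------------------------------------------
        xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
        axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
        bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
        tau_xr1 = axr1 * bxr1
        xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
        axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
        bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
        tau_xr2 = axr2 * bxr2

        # --- I_Ks gate ----------------------------------------------------
        xs_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
        axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
        bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
        tau_xs = axs * bxs + 80.0

        # --- I_to gates (epicardial) ---------------------------------------
        r_inf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
        tau_r = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
        s_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

        # --- I_CaL gates ---------------------------------------------------
        d_inf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
        ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
        gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
        tau_d = ad * bd + gd
        f_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
        af = 1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
        bf = 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
        gf = 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0
        tau_f = af + bf + gf
        f2_inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
        af2 = 600.0 * math.exp(-((V + 25.0) ** 2) / 170.0)
        bf2 = 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
        gf2 = 16.0 / (1.0 + math.exp((V + 30.0) / 10.0))
        tau_f2 = af2 + bf2 + gf2
        cass = y[15]
        fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
        tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

        # --- currents -----------------------------------------------------
        _human_currents_node(y, p, cur)
        i_ion = 0.0
        for c in range(12):
            i_ion += cur[c]

        # --- Ca dynamics ----------------------------------------------------
        cai = y[14]
        casr = y[16]
        kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
        k1 = 0.15 / kcasr
        k2 = 0.045 * kcasr
        rbar_inf = 0.005 / (k2 * cass + 0.005)
        tau_rbar = 1.0 / (k2 * cass + 0.005)
        o_gate = k1 * cass * cass * y[13] / (0.060 + k1 * cass * cass)
        j_rel = 0.102 * o_gate * (casr - cass)
        j_leak = 0.00036 * (casr - cai)
        j_up = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
        j_xfer = 0.0038 * (cass - cai)
        bufc = 1.0 / (1.0 + 0.2 * 0.001 / ((cai + 0.001) ** 2))
        bufsr = 1.0 / (1.0 + 10.0 * 0.3 / ((casr + 0.3) ** 2))
        bufss = 1.0 / (1.0 + 0.4 * 0.00025 / ((cass + 0.00025) ** 2))
        conv_c = 0.185 / (2.0 * 0.016404 * 96485.3415)
        dcai = bufc * (-(cur[11] + cur[8] - 2.0 * cur[6]) * conv_c
                       + (j_leak - j_up) * (0.001094 / 0.016404) + j_xfer)
        dcasr = bufsr * (j_up - j_rel - j_leak)
        dcass = bufss * (-cur[1] * 0.185 / (2.0 * 0.00005468 * 96485.3415)
                         + j_rel * 0.001094 / 0.00005468
                         - j_xfer * 0.016404 / 0.00005468)
        dnai = -(cur[0] + cur[10] + 3.0 * cur[7] + 3.0 * cur[6]) * (
            0.185 / (0.016404 * 96485.3415))
        dki = -(cur[5] + cur[2] + cur[3] + cur[4] - 2.0 * cur[7]
                + cur[9] - istim[k]) * (0.185 / (0.016404 * 96485.3415))

        # --- advance --------------------------------------------------------
        y[0] = V + dt * (-i_ion + istim[k])
        y[1] = m_inf + (y[1] - m_inf) * math.exp(-dt / tau_m)
        y[2] = h_inf + (y[2] - h_inf) * math.exp(-dt / tau_h)
        y[3] = j_inf + (y[3] - j_inf) * math.exp(-dt / tau_j)
        y[4] = xr1_inf + (y[4] - xr1_inf) * math.exp(-dt / tau_xr1)
        y[5] = xr2_inf + (y[5] - xr2_inf) * math.exp(-dt / tau_xr2)
        y[6] = xs_inf + (y[6] - xs_inf) * math.exp(-dt / tau_xs)
        y[7] = r_inf + (y[7] - r_inf) * math.exp(-dt / tau_r)
        y[8] = s_inf + (y[8] - s_inf) * math.exp(-dt / tau_s)
        y[9] = d_inf + (y[9] - d_inf) * math.exp(-dt / tau_d)
        y[10] = f_inf + (y[10] - f_inf) * math.exp(-dt / tau_f)
        y[11] = f2_inf + (y[11] - f2_inf) * math.exp(-dt / tau_f2)
        y[12] = fcass_inf + (y[12] - fcass_inf) * math.exp(-dt / tau_fcass)
        y[13] = rbar_inf + (y[13] - rbar_inf) * math.exp(-dt / tau_rbar)
        y[14] = cai + dt * dcai
        y[15] = cass + dt * dcass
        y[16] = casr + dt * dcasr
        y[17] = y[17] + dt * dnai
        y[18] = y[18] + dt * dki


# published initial conditions (quiescent steady state of the formulation)
_HUMAN_REST = np.array([
    -86.2, 0.0, 0.75, 0.75, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 1.0,
    1.0, 1.0, 0.00007, 0.00007, 1.3, 7.67, 138.3,
])


def build_human_model(params: dict[str, float] | None = None) -> MembraneModel:
    """Build the human epicardial ventricular myocyte model.

    params optionally overrides named maximal conductances (must be >= 0).
    """
    p = dict(_HUMAN_DEFAULTS)
    if params:
        for k, v in params.items():
            if k not in p:
                raise KeyError(f"unknown human parameter {k!r}")
            if v < 0:
                raise ValueError(f"parameter {k} must be non-negative")
            p[k] = float(v)
    pvec = np.array([p[name] for name in HUMAN_PARAM_NAMES], dtype=float)
    return MembraneModel(
        name="human-epicardial",
        state_names=HUMAN_STATE_NAMES,
        param_names=HUMAN_PARAM_NAMES,
        params=pvec,
        initial_state=_HUMAN_REST.copy(),
        current_names=HUMAN_CURRENT_NAMES,
        conductance_params=dict(_HUMAN_CONDUCTANCES),
        step_all=_human_step_all,
        currents_fn=_human_currents_node,
        resting_vm=-86.2,
        default_dt=0.02,
    )
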