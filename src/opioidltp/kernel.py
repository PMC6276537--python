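"""Fixed-step forward-Euler integration loop.

A single loop body serves both execution backends: the plain-Python
function below is compiled unchanged with ``numba.njit`` when numba is
importable.  The engine feeds the loop a pre-generated stream of uniform
random numbers (one per step) and the binomial VGCC draw is realised by
inverse-CDF lookup into that stream, so both backends consume the same
randomness and produce bit-identical trajectories for the same seed.

State vector layout (18 floats)::

    0 V      membrane potential (mV)
    1 m_A    AMPAR gating
    2 m_N    NMDAR gating
    3 g_VD   voltage-dependent NMDAR conductance (nS)
    4 c      spine calcium (uM)
    5..15    P0..P10 CaMKII phosphorylation states (uM)
    16 ep    active PP1 (uM)
    17 I1P   free phosphorylated inhibitor-1 (uM)

Recorded trace columns::

    0 t (ms), 1 V, 2 I_AMPA, 3 I_NMDA, 4 I_R, 5 c, 6 Ph.CaMKII, 7 g_AMPA
"""

from __future__ import annotations

import math

import numpy as np

from . import biophysics as bio
from .params import (
    FARADAY,
    GAS_CONSTANT,
    LADDER_COEFFS,
    ModelParameters,
    OpioidCondition,
)
from .stimulus import StimulusProtocol

N_STATE = 18
N_TRACE = 8

# autophosphorylation ladder coefficients; _A[i-1] scales the P_i -> P_{i+1}
# transition
_A = np.asarray(LADDER_COEFFS, dtype=np.float64)

# pvec layout -----------------------------------------------------------------
# 0 tau_post 1 V_rest 2 R_m(MOhm)
# 3 g_AMPA0 4 V_AMPA 5 alpha_A 6 beta_A 7 P_half 8 k_half
# 9 V_NMDA 10 alpha_N 11 beta_N 12 g_VI 13 tau_g 14 k_slope 15 V0
# 16 Mg_out 17 mg_K (effective affinity, mM) 18 mg_b (per mV)
# 19 g_op (opioid conductance increment, nS)
# 20 g_R 21 V_R 22 N_ch 23 Vh_open 24 k_open 25 vgcc_eff
# 26 eta 27 gamma 28 conv (uM/ms per pA) 29 Ks_ms 30 c_rest 31 b_t 32 K_endo
# 33 ep0 34 k3_ms 35 k4_ms 36 vCaN_ms 37 vPKAI0_ms 38 KH2 39 k1_ms
# 40 KH1 41 KM 42 k2_ms
# 43 amp (mM) 44 width (ms) 45 period (ms) 46 stim_end (ms)
N_PVEC = 47


def pack_params(mp: ModelParameters, protocol: StimulusProtocol,
                cond: OpioidCondition) -> np.ndarray:
    """Flatten parameters + condition + protocol into the kernel vector.

    All opioid dependence is resolved here (the effective Mg affinity,
    electrical distance and conductance increment are constants of a run),
    so the inner loop never evaluates the opioid terms.  Per-second cascade
    rates are converted to per-ms here, in one place.
    """
    mb, am, nm, vg, ca, cc = (mp.membrane, mp.ampar, mp.nmdar, mp.vgcc,
                              mp.calcium, mp.cascade)
    mg_K, delta_eff = bio._mg_affinity_and_delta(cond.Op, nm, cond.mg_effect_on)
    mg_b = nm.z * delta_eff * FARADAY * 1e-3 / (GAS_CONSTANT * nm.T)
    g_op = bio.nmdar_conductance(0.0, cond.Op, cond, nm) - nm.g_VI
    vgcc_eff = cond.vgcc_coeff if cond.vgcc_on else 0.0

    p = np.empty(N_PVEC)
    p[0:3] = (mb.tau_post, mb.V_rest, mb.R_m)
    p[3:9] = (am.g_AMPA0, am.V_AMPA, am.alpha_AMPA, am.beta_AMPA,
              am.P_half, am.k_half)
    p[9:16] = (nm.V_NMDA, nm.alpha_NMDA, nm.beta_NMDA, nm.g_VI, nm.tau_g,
               nm.k_slope, nm.V0)
    p[16:19] = (nm.Mg_out, mg_K, mg_b)
    p[19] = g_op
    p[20:26] = (vg.g_R, vg.V_R, float(vg.N), vg.Vh_open, vg.k_open, vgcc_eff)
    p[26:33] = (ca.eta, ca.gamma, ca.current_to_flux, ca.K_s * 1e-3,
                ca.c_rest, ca.b_t, ca.K_endo)
    p[33:43] = (cc.e_p0, cc.k3 * 1e-3, cc.k4 * 1e-3, cc.v_CaN * 1e-3,
                cc.v_PKA * cc.I_0 * 1e-3, cc.K_H2, cc.k1 * 1e-3,
                cc.K_H1, cc.K_M, cc.k2 * 1e-3)
    p[43:47] = (protocol.amplitude, protocol.pulse_width, protocol.period,
                protocol.duration_ms)
    return p


def initial_state(mp: ModelParameters) -> np.ndarray:
    """Resting initial condition: V_rest, closed gates, P0 = total CaMKII,
    PP1/I1P at their resting equilibrium."""
    from .cascade import resting_pp1_equilibrium

    y = np.zeros(N_STATE)
    y[0] = mp.membrane.V_rest
    y[4] = mp.calcium.c_rest
    y[5] = mp.cascade.camkii_total
    ep, i1p = resting_pp1_equilibrium(mp.cascade, mp.calcium.c_rest)
    y[16] = ep
    y[17] = i1p
    return y


def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-min(x, 700.0)))
    e = math.exp(max(x, -700.0))
    return e / (1.0 + e)


def _binomial_inv(u: float, n: int, pr: float) -> int:
    """Binomial quantile by sequential inverse-CDF lookup (small n)."""
    if pr <= 0.0 or n == 0:
        return 0
    if pr >= 1.0 - 1e-12:
        return n
    q = 1.0 - pr
    pmf = q ** n
    cdf = pmf
    k = 0
    while u > cdf and k < n:
        pmf *= (n - k) / (k + 1.0) * (pr / q)
        k += 1
        cdf += pmf
    return k


def euler_loop(y, p, n_steps, dt, stride, u, trace):
    """Integrate ``n_steps`` forward-Euler steps, updating ``y`` in place.

    Returns ``(status, bad_var, bad_step, n_breach)``: status 0 is success,
    status 1 flags the first non-finite state variable (index ``bad_var``
    after step ``bad_step``).  ``trace`` must have ``n_steps // stride + 1``
    rows; ``u`` holds one uniform variate per step, consumed only by the
    VGCC draw.
    """
    n_breach = 0
    rec = 0
    n_ch = int(p[22])
    Pold = np.empty(11)
    for i in range(n_steps + 1):
        t = i * dt
        # --- stimulus -------------------------------------------------
        g_pre = 0.0
        if t < p[46] and (t % p[45]) < p[44]:
            g_pre = p[43]

        V = y[0]
        m_A = y[1]
        m_N = y[2]
        g_VD = y[3]
        c = y[4]
        ep = y[16]
        i1p = y[17]

        # --- conductances and Mg block --------------------------------
        phospho = 0.0
        for j in range(6, 16):
            phospho += y[j]
        g_ampa = p[3] * (1.0 + _sigmoid((phospho - p[7]) / p[8]))
        mg = 1.0 / (1.0 + p[16] / p[17] * math.exp(min(-p[18] * V, 700.0)))
        g_nmda = p[12] + p[19] + g_VD

        # --- currents (the VGCC draw consumes u[i]) -------------------
        I_A = g_ampa * m_A * (V - p[4])
        I_N = g_nmda * m_N * mg * (V - p[9])
        I_R = 0.0
        if p[25] > 0.0 and n_ch > 0 and i < n_steps:
            p_open = _sigmoid((V - p[23]) / p[24])
            n_open = _binomial_inv(u[i], n_ch, p_open)
            if n_open > 0:
                I_R = p[25] * p[20] * n_open * (V - p[21])

        # --- record ---------------------------------------------------
        if i % stride == 0:
            trace[rec, 0] = t
            trace[rec, 1] = V
            trace[rec, 2] = I_A
            trace[rec, 3] = I_N
            trace[rec, 4] = I_R
            trace[rec, 5] = c
            trace[rec, 6] = phospho
            trace[rec, 7] = g_ampa
            rec += 1
        if i == n_steps:
            break

        # --- membrane, gating, g_VD, calcium derivatives --------------
        I_syn = -(I_A + I_N)
        dV = (-(V - p[1]) + p[2] * I_syn * 1e-3) / p[0]
        dmA = p[5] * g_pre * (1.0 - m_A) - p[6] * m_A
        dmN = p[10] * g_pre * (1.0 - m_N) - p[11] * m_N
        g_inf = p[14] * (V - p[15])
        if g_inf < 0.0:
            g_inf = 0.0
        dgVD = (g_inf - g_VD) / p[13]
        influx = -(p[26] * I_A + p[27] * I_N + I_R) * p[28]
        theta = p[31] * p[32] / ((p[32] + c) * (p[32] + c))
        dc = (influx - p[29] * (c - p[30])) / (1.0 + theta)

        # --- cascade derivatives (rates pre-converted to per ms) ------
        r4 = (c / p[40]) ** 4
        v1 = 10.0 * p[39] * r4 * r4 / ((1.0 + r4) * (1.0 + r4)) * y[5]
        v2 = p[39] * r4 / (1.0 + r4)
        wsum = 0.0
        for j in range(1, 11):
            wsum += j * y[5 + j]
        v3 = p[42] * ep / (p[41] + wsum)
        binding = -p[34] * i1p * ep + p[35] * (p[33] - ep)
        h2 = (c / p[38]) ** 3
        dI1P = binding + p[37] - p[36] * h2 / (1.0 + h2) * i1p

        # --- Euler update ---------------------------------------------
        y[0] = V + dt * dV
        y[1] = m_A + dt * dmA
        y[2] = m_N + dt * dmN
        y[3] = g_VD + dt * dgVD
        y[4] = c + dt * dc
        # CaMKII ladder on a frozen copy of the old rungs; the fluxes
        # telescope so that sum(dP) == 0 exactly
        for j in range(11):
            Pold[j] = y[5 + j]
        y[5] = Pold[0] + dt * (-v1 + v3 * Pold[1])
        y[6] = Pold[1] + dt * (v1 - v3 * Pold[1] - _A[0] * v2 * Pold[1]
                               + 2.0 * v3 * Pold[2])
        for j in range(2, 10):
            y[5 + j] = Pold[j] + dt * (
                _A[j - 2] * v2 * Pold[j - 1] - j * v3 * Pold[j]
                - _A[j - 1] * v2 * Pold[j] + (j + 1.0) * v3 * Pold[j + 1])
        y[15] = Pold[10] + dt * (_A[8] * v2 * Pold[9] - 10.0 * v3 * Pold[10])
        y[16] = ep + dt * binding
        y[17] = i1p + dt * dI1P

        # --- clamping with breach accounting --------------------------
        breached = False
        if y[1] < 0.0:
            y[1] = 0.0
            breached = True
        elif y[1] > 1.0:
            y[1] = 1.0
            breached = True
        if y[2] < 0.0:
            y[2] = 0.0
            breached = True
        elif y[2] > 1.0:
            y[2] = 1.0
            breached = True
        if y[3] < 0.0:
            y[3] = 0.0
            breached = True
        if y[4] < 0.0:
            y[4] = 0.0
            breached = True
        for j in range(5, 16):
            if y[j] < 0.0:
                y[j] = 0.0
                breached = True
        if y[16] < 0.0:
            y[16] = 0.0
            breached = True
        elif y[16] > p[33]:
            y[16] = p[33]
            breached = True
        if y[17] < 0.0:
            y[17] = 0.0
            breached = True
        if breached:
            n_breach += 1

        for j in range(N_STATE):
            if not math.isfinite(y[j]):
                return 1, j, i + 1, n_breach
    return 0, -1, -1, n_breach


# ---------------------------------------------------------------------------
# numba fast path: identical source, compiled.
try:  # pragma: no cover - exercised implicitly by the engine
    from numba import njit

    _sigmoid_py = _sigmoid
    _binomial_inv_py = _binomial_inv
    _sigmoid = njit(cache=False)(_sigmoid)
    _binomial_inv = njit(cache=False)(_binomial_inv)
    euler_loop_python = euler_loop

    def _rebind_python_loop():
        """Recreate the pure-Python loop with the un-jitted helpers."""
        import types

        g = dict(euler_loop.__globals__)
        g["_sigmoid"] = _sigmoid_py
        g["_binomial_inv"] = _binomial_inv_py
        return types.FunctionType(euler_loop.__code__, g,
                                  euler_loop.__name__,
                                  euler_loop.__defaults__)

    euler_loop_python = _rebind_python_loop()
    euler_loop_numba = njit(cache=False)(euler_loop)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    euler_loop_python = euler_loop
    euler_loop_numba = None
    HAVE_NUMBA = False
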