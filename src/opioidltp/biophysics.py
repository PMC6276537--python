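"""Membrane, receptor, channel and calcium right-hand sides.

These functions are the readable reference implementation of the spine
biophysics; the production integrator (:mod:`opioidltp.kernel`) inlines the
same expressions for speed, and the test suite asserts that the two paths
produce identical trajectories.

Sign conventions: currents are positive outward, so synaptic currents at
sub-reversal potentials are negative (inward) and inward currents raise
both the membrane potential (through ``I_syn = -(I_AMPA + I_NMDA)``) and
spine calcium.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ModelConsistencyError
from .params import (
    AMPARParameters,
    CalciumParameters,
    FARADAY,
    GAS_CONSTANT,
    MembraneParameters,
    NMDARParameters,
    OpioidCondition,
    VGCCParameters,
)

__all__ = [
    "opioid_saturation",
    "mg_block",
    "nmdar_conductance",
    "g_vd_derivative",
    "receptor_gating_derivative",
    "ampar_current",
    "nmdar_current",
    "ampar_conductance_from_camkii",
    "vgcc_open_probability",
    "vgcc_current",
    "calcium_derivative",
    "pump_rate",
    "membrane_derivative",
]


def opioid_saturation(Op: float, p: NMDARParameters) -> float:
    """Saturating opioid occupancy factor s(Op) in [0, 1).

    ``s = (op_scale*Op)^op_exp / (1 + (op_scale*Op)^op_exp)``; zero without
    opioid, approaching one at saturating concentrations.
    """
    if Op <= 0:
        return 0.0
    x = (p.op_scale * Op) ** p.op_exp
    return x / (1.0 + x)


def _mg_affinity_and_delta(Op: float, p: NMDARParameters, mg_effect_on: bool):
    """Effective Mg affinity constant K (mM) and electrical distance."""
    if p.opioid_form == "printed":
        # Literal printed form: both terms decay as 1/(1 + (0.1 Op)^1.2).
        decay = 1.0 / (1.0 + (0.1 * Op) ** 1.2) if (mg_effect_on and Op > 0) \
            else 1.0
        return p.k0 + p.mg_k_shift * decay, p.delta + p.mg_delta_shift * decay
    s = opioid_saturation(Op, p) if mg_effect_on else 0.0
    return p.k0 + p.mg_k_shift * s, p.delta + p.mg_delta_shift * (1.0 - s)


def mg_block(V: float, Op: float, p: NMDARParameters,
             mg_effect_on: bool = True) -> float:
    """Voltage-dependent Mg2+ block factor in (0, 1].

    Woodhull-type expression: depolarization relieves the block
    (factor -> 1 as V -> +inf, -> 0 as V -> -inf) and opioids weaken it by
    raising the Mg affinity constant and lowering the effective electrical
    distance of the blocking site.  With ``mg_effect_on=False`` the
    opioid-dependent terms are frozen at their Op = 0 values.
    """
    K, delta_eff = _mg_affinity_and_delta(Op, p, mg_effect_on)
    # exponent per mV: z * delta_eff * F / (R T) with V in volts (1e-3 factor)
    b = p.z * delta_eff * FARADAY * 1e-3 / (GAS_CONSTANT * p.T)
    return 1.0 / (1.0 + p.Mg_out / K * math.exp(-b * V))


def nmdar_conductance(g_VD: float, Op: float, cond: OpioidCondition,
                      p: NMDARParameters) -> float:
    """Total NMDAR conductance g_NMDA = g_VI + opioid term + g_VD (nS).

    The opioid term is a voltage-independent increment
    ``nmdar_coeff * cond_sat * s(Op)`` (saturating at 0.15 nS for unit
    coefficient); it vanishes for Op = 0 and is forced to zero when the
    condition's conductance mechanism is switched off (the "CK=0" run).
    """
    term = 0.0
    if cond.conductance_effect_on and Op > 0:
        if p.opioid_form == "printed":
            term = cond.nmdar_coeff * p.cond_sat / (1.0 + (0.1 * Op) ** 1.2)
        else:
            term = cond.nmdar_coeff * p.cond_sat * opioid_saturation(Op, p)
    g = p.g_VI + term + g_VD
    if g < 0:
        raise ModelConsistencyError(f"negative NMDAR conductance: {g}")
    return g


def g_vd_derivative(g_VD: float, V: float, p: NMDARParameters) -> float:
    """Relaxation of the voltage-dependent NMDAR conductance (nS/ms).

    ``g_VD`` relaxes toward ``g_VD_inf = k_slope * (V - V0)`` with time
    constant ``tau_g``; the target is floored at zero because a conductance
    cannot be negative.
    """
    g_inf = p.k_slope * (V - p.V0)
    if g_inf < 0.0:
        g_inf = 0.0
    return (g_inf - g_VD) / p.tau_g


def receptor_gating_derivative(m: float, g_pre: float, alpha: float,
                               beta: float) -> float:
    """Two-state kinetic gate: dm/dt = alpha*g_pre*(1-m) - beta*m (per ms).

    Shared by AMPAR and NMDAR gating; ``g_pre`` is glutamate in mM.
    """
    return alpha * g_pre * (1.0 - m) - beta * m


def ampar_current(V: float, m_AMPA: float, g_AMPA: float,
                  p: AMPARParameters) -> float:
    """AMPAR current g_AMPA * m * (V - V_AMPA) in pA (nS * mV)."""
    return g_AMPA * m_AMPA * (V - p.V_AMPA)


def nmdar_current(V: float, m_NMDA: float, g_NMDA: float, Mg: float,
                  p: NMDARParameters) -> float:
    """NMDAR current g_NMDA * m * Mg * (V - V_NMDA) in pA."""
    return g_NMDA * m_NMDA * Mg * (V - p.V_NMDA)


def ampar_conductance_from_camkii(phospho: float, p: AMPARParameters) -> float:
    """AMPAR conductance enhanced by phosphorylated CaMKII (nS).

    ``g_AMPA0 * (1 + sigmoid((phospho - P_half)/k_half))``: bounded in
    (g_AMPA0, 2 g_AMPA0), equal to 1.5x baseline at ``phospho = P_half``.
    """
    x = (phospho - p.P_half) / p.k_half
    if x >= 0:
        sig = 1.0 / (1.0 + math.exp(-x))
    else:  # overflow-safe branch for the deeply unphosphorylated regime
        e = math.exp(x)
        sig = e / (1.0 + e)
    return p.g_AMPA0 * (1.0 + sig)


def vgcc_open_probability(V: float, p: VGCCParameters) -> float:
    """Logistic open probability of a high-voltage-activated channel."""
    return 1.0 / (1.0 + math.exp(-(V - p.Vh_open) / p.k_open))


def vgcc_current(V: float, cond: OpioidCondition, p: VGCCParameters,
                 rng: np.random.RandomState | np.random.Generator) -> float:
    """Stochastic VGCC current (pA): one binomial draw of open channels.

    ``n_open ~ Binomial(N, P_open(V))``; the current is
    ``vgcc_coeff * g_R * n_open * (V - V_R)`` and exactly zero when the
    condition disables VGCCs (the "Icr=0" run).
    """
    if not cond.vgcc_on or cond.vgcc_coeff == 0.0 or p.N == 0:
        return 0.0
    n_open = int(rng.binomial(p.N, vgcc_open_probability(V, p)))
    return cond.vgcc_coeff * p.g_R * n_open * (V - p.V_R)


def pump_rate(c: float, p: CalciumParameters) -> float:
    """Calcium pump flux K_s * (c - c_rest), returned in uM/ms.

    Linear and symmetric about rest: above-rest calcium is extruded,
    below-rest calcium relaxes back up.
    """
    return p.K_s * 1e-3 * (c - p.c_rest)


def calcium_derivative(c: float, I_AMPA: float, I_NMDA: float, I_R: float,
                       p: CalciumParameters) -> float:
    """Spine free-calcium derivative (uM/ms) with rapid buffering.

    ``dc/dt = f(c) / (1 + theta(c))`` with
    ``f = -(eta*I_AMPA + gamma*I_NMDA + I_R) / (Z F V_spine) - S_pump`` and
    ``theta = b_t K_endo / (K_endo + c)^2``.  Inward (negative) currents
    raise calcium.  The pA -> uM/ms conversion is
    :attr:`CalciumParameters.current_to_flux`.
    """
    if c < 0:
        raise ModelConsistencyError(f"negative calcium concentration: {c}")
    influx = -(p.eta * I_AMPA + p.gamma * I_NMDA + I_R) * p.current_to_flux
    theta = p.b_t * p.K_endo / (p.K_endo + c) ** 2
    return (influx - pump_rate(c, p)) / (1.0 + theta)


def membrane_derivative(V: float, I_AMPA: float, I_NMDA: float,
                        p: MembraneParameters) -> float:
    """Passive membrane: dV/dt = (-(V - V_rest) + R_m I_syn) / tau_post.

    ``I_syn = -(I_AMPA + I_NMDA)`` (VGCC current feeds calcium only, not the
    membrane).  With R_m in MOhm and currents in pA, ``R_m * I_syn`` is in
    uV, hence the 1e-3 factor to mV.
    """
    I_syn = -(I_AMPA + I_NMDA)
    return (-(V - p.V_rest) + p.R_m * I_syn * 1e-3) / p.tau_post
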