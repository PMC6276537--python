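"""CaMKII phosphorylation ladder with PP1 / inhibitor-1 regulation.

The holoenzyme is modelled as eleven phosphorylation states P0..P10
(concentrations of 0- to 10-fold phosphorylated CaMKII, in uM of subunit).
Calcium drives the initial phosphorylation (v1, a steep eighth-order Hill
term acting on P0) and subunit-to-subunit autophosphorylation (v2, fourth
order) with the ladder coefficients 1, 1, 1.8, 2.3, 2.7, 2.8, 2.7, 2.3,
1.8, 1; active PP1 dephosphorylates rung by rung (v3, with an i-fold
multiplier on the i-th state).  PP1 itself is inactivated by binding
phosphorylated inhibitor-1 (I1P), which PKA produces at a constant rate and
calcineurin destroys in a calcium-dependent manner — together a bistable
phosphatase switch.

All rates here are per second; the integration engine converts to per-ms in
a single place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ModelConsistencyError
from .params import CascadeParameters, LADDER_COEFFS

__all__ = [
    "CascadeState",
    "cascade_rates",
    "cascade_derivatives",
    "phosphorylated_camkii",
    "resting_pp1_equilibrium",
    "initial_cascade_state",
]


@dataclass
class CascadeState:
    """Concentrations of the cascade species (uM)."""

    P: np.ndarray = field(default_factory=lambda: np.zeros(11))
    ep: float = 0.0    # active (unbound) PP1
    I1P: float = 0.0   # free phosphorylated inhibitor-1

    def validate(self, p: CascadeParameters) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (11,):
            raise ParameterError("P must hold the 11 states P0..P10")
        if np.any(P < 0) or self.ep < 0 or self.I1P < 0:
            raise ModelConsistencyError("cascade concentrations must be >= 0")
        if self.ep > p.e_p0 * (1 + 1e-9):
            raise ModelConsistencyError("active PP1 cannot exceed total PP1")


def cascade_rates(c_post: float, state: CascadeState,
                  p: CascadeParameters) -> tuple[float, float, float]:
    """Phosphorylation (v1, uM/s), autophosphorylation (v2, /s) and
    dephosphorylation (v3, /s) rates at calcium ``c_post`` (uM).

    v1 = 10 k1 (c/K_H1)^8 P0 / (1 + (c/K_H1)^4)^2
    v2 = k1 (c/K_H1)^4 / (1 + (c/K_H1)^4)
    v3 = k2 ep / (K_M + sum_i i * P_i)
    """
    if c_post < 0:
        raise ModelConsistencyError("calcium must be >= 0")
    r4 = (c_post / p.K_H1) ** 4
    v1 = 10.0 * p.k1 * r4 * r4 / (1.0 + r4) ** 2 * float(state.P[0])
    v2 = p.k1 * r4 / (1.0 + r4)
    weighted = float(np.dot(np.arange(11.0), state.P))
    v3 = p.k2 * state.ep / (p.K_M + weighted)
    return v1, v2, v3


def cascade_derivatives(c_post: float, state: CascadeState,
                        p: CascadeParameters) -> CascadeState:
    """Time derivatives of the cascade state (per second).

    The eleven ladder equations telescope: the sum of all dP_i/dt is
    identically zero, so total CaMKII is conserved exactly — including under
    forward Euler.
    """
    state.validate(p)
    v1, v2, v3 = cascade_rates(c_post, state, p)
    P = np.asarray(state.P, dtype=float)
    dP = np.zeros(11)
    # forward (autophosphorylation) fluxes a_i * v2 * P_i for i = 1..9
    fwd = np.zeros(11)
    for i, a in enumerate(LADDER_COEFFS, start=1):
        fwd[i] = a * v2 * P[i]
    # backward (dephosphorylation) fluxes i * v3 * P_i for i = 1..10
    back = np.arange(11.0) * v3 * P
    dP[0] = -v1 + back[1]
    dP[1] = v1 - back[1] - fwd[1] + back[2]
    for i in range(2, 10):
        dP[i] = fwd[i - 1] - back[i] - fwd[i] + back[i + 1]
    dP[10] = fwd[9] - back[10]

    ex = p.e_p0 - state.ep  # PP1 bound in the PP1-I1P complex
    binding = -p.k3 * state.I1P * state.ep + p.k4 * ex
    hill2 = (c_post / p.K_H2) ** 3
    dI1P = binding + p.v_PKA * p.I_0 \
        - p.v_CaN * hill2 / (1.0 + hill2) * state.I1P
    return CascadeState(P=dP, ep=binding, I1P=dI1P)


def phosphorylated_camkii(state: CascadeState) -> float:
    """Total phosphorylated CaMKII: sum of P1..P10 (P0 excluded), in uM."""
    return float(np.sum(np.asarray(state.P, dtype=float)[1:]))


def resting_pp1_equilibrium(p: CascadeParameters,
                            c_rest: float) -> tuple[float, float]:
    """(ep, I1P) equilibrium of the PP1/I1 subsystem at resting calcium.

    Setting dI1P/dt - dep/dt = 0 gives the I1P balance between PKA
    production and calcineurin degradation,
    ``I1P* = v_PKA I_0 / (v_CaN H3(c_rest))``; the binding equilibrium then
    fixes ``ep* = k4 e_p0 / (k4 + k3 I1P*)``.  At typical resting calcium
    the phosphatase is almost fully inhibited.
    """
    hill = (c_rest / p.K_H2) ** 3
    h3 = hill / (1.0 + hill)
    if h3 <= 0:
        raise ParameterError(
            "resting calcium must be positive for a PP1 equilibrium to exist")
    I1P = p.v_PKA * p.I_0 / (p.v_CaN * h3)
    ep = p.k4 * p.e_p0 / (p.k4 + p.k3 * I1P)
    return ep, I1P


def initial_cascade_state(p: CascadeParameters, c_rest: float) -> CascadeState:
    """Fully unphosphorylated holoenzyme with PP1/I1P at rest equilibrium."""
    P = np.zeros(11)
    P[0] = p.camkii_total
    ep, I1P = resting_pp1_equilibrium(p, c_rest)
    return CascadeState(P=P, ep=ep, I1P=I1P)
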