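import numpy as np
import pytest

from opioidltp import (
    ModelParameters,
    OpioidCondition,
    SimulationConfig,
    StimulusProtocol,
    simulate,
)
from opioidltp import kernel
from opioidltp import biophysics as bio
from opioidltp.cascade import CascadeState, cascade_derivatives, phosphorylated_camkii


@pytest.fixture
def params():
    """Fresh copy of the shipped calibrated parameter set."""
    return ModelParameters()


@pytest.fixture
def protocol():
    """Standard stimulus: 5 Hz, 4 ms pulses, 0.2 mM, 10 s."""
    return StimulusProtocol()


def reference_trajectory(params, protocol, cond, t_end_ms, sample_ms=1.0):
    """Adaptive-step oracle for the deterministic sub-model (VGCCs off).

    Integrates the same right-hand sides with LSODA piecewise between the
    glutamate pulse edges (the input is discontinuous there), at tight
    tolerances, and returns (times, states) sampled every ``sample_ms``.
    Independent of the forward-Euler production path.
    """
    from scipy.integrate import solve_ivp

    assert not cond.vgcc_on or cond.vgcc_coeff == 0

    def rhs(t, y, g_pre):
        V, mA, mN, gVD, c = y[:5]
        c = max(c, 0.0)
        st = CascadeState(P=np.clip(y[5:16], 0, None),
                          ep=min(max(y[16], 0.0), params.cascade.e_p0),
                          I1P=max(y[17], 0.0))
        ph = phosphorylated_camkii(st)
        gA = bio.ampar_conductance_from_camkii(ph, params.ampar)
        mg = bio.mg_block(V, cond.Op, params.nmdar, cond.mg_effect_on)
        gN = bio.nmdar_conductance(max(gVD, 0.0), cond.Op, cond, params.nmdar)
        IA = bio.ampar_current(V, mA, gA, params.ampar)
        IN = bio.nmdar_current(V, mN, gN, mg, params.nmdar)
        d = np.empty(18)
        d[0] = bio.membrane_derivative(V, IA, IN, params.membrane)
        d[1] = bio.receptor_gating_derivative(
            mA, g_pre, params.ampar.alpha_AMPA, params.ampar.beta_AMPA)
        d[2] = bio.receptor_gating_derivative(
            mN, g_pre, params.nmdar.alpha_NMDA, params.nmdar.beta_NMDA)
        d[3] = bio.g_vd_derivative(gVD, V, params.nmdar)
        d[4] = bio.calcium_derivative(c, IA, IN, 0.0, params.calcium)
        dc = cascade_derivatives(c, st, params.cascade)
        d[5:16] = dc.P * 1e-3  # cascade rates are per second
        d[16] = dc.ep * 1e-3
        d[17] = dc.I1P * 1e-3
        return d

    edges = [0.0]
    t = 0.0
    while t < t_end_ms:
        edges += [t + protocol.pulse_width, t + protocol.period]
        t += protocol.period
    edges = sorted(e for e in edges if e < t_end_ms) + [t_end_ms]

    y = kernel.initial_state(params)
    ts_all, ys_all = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        g = protocol.amplitude if (a % protocol.period) < protocol.pulse_width \
            and a < protocol.duration_ms else 0.0
        sol = solve_ivp(rhs, (a, b), y, args=(g,), method="LSODA",
                        rtol=1e-8, atol=1e-10, dense_output=True, max_step=1.0)
        assert sol.success
        y = sol.y[:, -1]
        tt = np.arange(np.ceil(a / sample_ms) * sample_ms, b + 1e-9, sample_ms)
        if len(tt):
            ts_all.append(tt)
            ys_all.append(sol.sol(tt))
    return np.concatenate(ts_all), np.hstack(ys_all)


@pytest.fixture
def reference_oracle():
    return reference_trajectory
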