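"""Simulation engine: state assembly, forward-Euler integration, recording.

The production integrator is the paper-style fixed-step forward Euler
scheme (default dt = 0.05 ms over a 10 s horizon).  One binomial VGCC draw
is made per step from a seeded stream, so a run is a pure function of
(parameters, protocol, condition, config, seed): identical inputs give
bit-identical traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import kernel
from .errors import IntegrationError, ParameterError, StateCorruptionError
from .params import ModelParameters, OpioidCondition
from .stimulus import StimulusProtocol

#: Names of the state-vector entries (for error reporting).
STATE_NAMES = ("V", "m_AMPA", "m_NMDA", "g_VD", "c_post",
               "P0", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9",
               "P10", "ep", "I1P")

TRACE_COLUMNS = ("t_ms", "V", "I_AMPA", "I_NMDA", "I_R", "c_post",
                 "phospho_camkii", "g_AMPA")

#: Fraction of steps allowed to need invariant clamping before a run is
#: declared corrupted.
BREACH_TOLERANCE = 1e-4


@dataclass
class SimulationConfig:
    """Integration settings."""

    dt: float = 0.05          # step size (ms)
    t_end: float = 10.0       # horizon (s)
    seed: int = 0             # RNG seed for the VGCC stream
    record_stride: int = 20   # steps between recorded samples (20 -> 1 ms)

    def validate(self) -> None:
        if not self.dt > 0:
            raise ParameterError("dt must be > 0")
        if not self.t_end > 0:
            raise ParameterError("t_end must be > 0")
        if self.record_stride < 1:
            raise ParameterError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end * 1000.0 / self.dt))


@dataclass
class SimulationResult:
    """Recorded traces plus summary scalars of one run."""

    trace: pd.DataFrame
    final_state: np.ndarray
    peak_phospho: float       # peak phosphorylated CaMKII (uM)
    final_phospho: float      # end-of-run phosphorylated CaMKII (uM)
    final_g_ampa: float       # end-of-run AMPAR conductance (nS)
    ltp_induced: bool
    n_breach: int
    config: SimulationConfig
    params: dict = field(repr=False, default_factory=dict)

    def summary(self) -> dict:
        return {
            "peak_phospho_camkii_uM": self.peak_phospho,
            "final_phospho_camkii_uM": self.final_phospho,
            "final_g_ampa_nS": self.final_g_ampa,
            "ltp_induced": bool(self.ltp_induced),
            "n_invariant_breaches": int(self.n_breach),
        }

    def summary_json(self) -> str:
        return json.dumps({"summary": self.summary(),
                           "parameters": self.params}, indent=2)


def ltp_detect(result: SimulationResult | np.ndarray,
               threshold: float = 40.0) -> bool:
    """LTP flag: peak phosphorylated CaMKII strictly above ``threshold`` (uM).

    The default threshold is the AMPAR-phosphorylation midpoint P_half.
    """
    if isinstance(result, SimulationResult):
        peak = float(result.trace["phospho_camkii"].max())
    else:
        peak = float(np.max(result))
    return peak > threshold


def simulate(params: ModelParameters,
             protocol: StimulusProtocol | None = None,
             cond: OpioidCondition | None = None,
             cfg: SimulationConfig | None = None,
             backend: str = "auto") -> SimulationResult:
    """Run one forward-Euler trajectory of the full spine model.

    Parameters
    ----------
    params, protocol, cond, cfg
        Model parameters, glutamate pulse train, opioid condition and
        integration settings (defaults: calibrated parameters, standard
        5 Hz / 4 ms / 0.2 mM stimulus, opioid-free condition, 0.05 ms steps
        for 10 s with seed 0).
    backend
        "numba" (fast, default when available), "python", or "auto".

    Raises
    ------
    IntegrationError
        If any state variable becomes non-finite (names the variable and
        the simulation time).
    StateCorruptionError
        If invariant clamping was needed in more than 1e-4 of the steps.
    """
    protocol = protocol or StimulusProtocol()
    cond = cond or OpioidCondition.normal()
    cfg = cfg or SimulationConfig()
    params.validate()
    protocol.validate()
    cond.validate()
    cfg.validate()

    if backend == "auto":
        backend = "numba" if kernel.HAVE_NUMBA else "python"
    if backend == "numba":
        if not kernel.HAVE_NUMBA:
            raise ParameterError("numba backend requested but numba is absent")
        loop = kernel.euler_loop_numba
    elif backend == "python":
        loop = kernel.euler_loop_python
    else:
        raise ParameterError(f"unknown backend {backend!r}")

    n_steps = cfg.n_steps
    y = kernel.initial_state(params)
    pvec = kernel.pack_params(params, protocol, cond)
    rng = np.random.RandomState(int(cfg.seed) % (2 ** 31))
    u = rng.random_sample(n_steps)
    n_rec = n_steps // cfg.record_stride + 1
    trace = np.empty((n_rec, kernel.N_TRACE))

    status, bad_var, bad_step, n_breach = loop(
        y, pvec, n_steps, float(cfg.dt), int(cfg.record_stride), u, trace)

    if status == 1:
        raise IntegrationError(STATE_NAMES[bad_var], bad_step * cfg.dt)
    if n_breach > BREACH_TOLERANCE * n_steps:
        raise StateCorruptionError(
            f"state invariants clamped in {n_breach} of {n_steps} steps "
            f"(tolerance {BREACH_TOLERANCE:g})")

    df = pd.DataFrame(trace, columns=list(TRACE_COLUMNS))
    peak = float(df["phospho_camkii"].max())
    final = float(df["phospho_camkii"].iloc[-1])
    result = SimulationResult(
        trace=df,
        final_state=y,
        peak_phospho=peak,
        final_phospho=final,
        final_g_ampa=float(df["g_AMPA"].iloc[-1]),
        ltp_induced=peak > params.ampar.P_half,
        n_breach=n_breach,
        config=cfg,
        params={"model": params.to_dict(),
                "stimulus": vars(protocol).copy(),
                "condition": vars(cond).copy(),
                "simulation": vars(cfg).copy()},
    )
    return result


def convergence_check(params: ModelParameters,
                      protocol: StimulusProtocol,
                      cond: OpioidCondition,
                      cfg: SimulationConfig,
                      dt_list: Sequence[float],
                      record_every_ms: float = 1.0) -> dict[float, dict]:
    """Self-convergence of the deterministic sub-model across step sizes.

    Reruns the model with VGCCs disabled at each ``dt`` and reports the
    maximum deviation of the V and calcium traces from the smallest-dt run,
    sampled on a common grid (every ``record_every_ms``).  Each ``dt`` must
    divide the sampling interval.
    """
    det = OpioidCondition(**{**vars(cond), "vgcc_on": False})
    dts = sorted(set(float(d) for d in dt_list))
    traces = {}
    for dt in dts:
        stride = record_every_ms / dt
        if abs(stride - round(stride)) > 1e-9:
            raise ParameterError(
                f"dt={dt} must divide the sampling interval {record_every_ms}")
        c = SimulationConfig(dt=dt, t_end=cfg.t_end, seed=cfg.seed,
                             record_stride=int(round(stride)))
        traces[dt] = simulate(params, protocol, det, c).trace
    ref = traces[dts[0]]
    n = min(len(t) for t in traces.values())
    out = {}
    for dt in dts:
        tr = traces[dt]
        out[dt] = {
            "max_dV": float(np.max(np.abs(tr["V"].values[:n]
                                          - ref["V"].values[:n]))),
            "max_dc": float(np.max(np.abs(tr["c_post"].values[:n]
                                          - ref["c_post"].values[:n]))),
        }
    return out
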