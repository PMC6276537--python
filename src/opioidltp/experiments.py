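"""Condition comparisons and parameter sweeps.

Reproduces the model's headline analyses: the five-condition comparison
(normal, opioid, and the three mechanism knockouts CK=0 / CMg=0 / Icr=0),
the NMDAR-conductance and VGCC coefficient sweeps, and the glutamate
amplitude and frequency sweeps.  Summary scalars of stochastic runs are
averaged over a seed list (default 5 seeds) before min-max normalization.

"Phosphorylated AMPAR" is quantified as the end-of-run AMPAR conductance
increase above baseline (final g_AMPA - g_AMPA0), the only
AMPAR-phosphorylation observable the model defines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationConfig, simulate
from .errors import DegenerateNormalizationError
from .params import ModelParameters, OpioidCondition
from .stimulus import StimulusProtocol

FIVE_CONDITION_LABELS = ("normal", "opioid", "CK=0", "CMg=0", "Icr=0")

DEFAULT_N_SEEDS = 5


@dataclass
class ConditionResult:
    """Seed-averaged summary of one condition."""

    label: str
    raw_phospho_camkii: float       # peak Ph.CaMKII, uM
    raw_phospho_ampar: float        # final g_AMPA - g_AMPA0, nS
    ltp_fraction: float             # fraction of seeds with the LTP flag
    normalized_camkii: float = float("nan")
    normalized_ampar: float = float("nan")


@dataclass
class SweepResult:
    """One summary row per grid value of a swept parameter."""

    parameter: str
    grid: np.ndarray
    conditions: list[ConditionResult]
    threshold: float | None = None  # detected grid value, if any

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "value": self.grid,
            "phospho_camkii_uM": [c.raw_phospho_camkii for c in self.conditions],
            "phospho_ampar_nS": [c.raw_phospho_ampar for c in self.conditions],
            "normalized_camkii": [c.normalized_camkii for c in self.conditions],
            "normalized_ampar": [c.normalized_ampar for c in self.conditions],
            "ltp_fraction": [c.ltp_fraction for c in self.conditions],
        })


def normalize(values: Sequence[float]) -> np.ndarray:
    """Min-max normalization (Y - Ymin) / (Ymax - Ymin), elementwise in [0, 1].

    All-equal input is a degenerate case (the formula divides by zero) and
    raises :class:`DegenerateNormalizationError`.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise DegenerateNormalizationError(
            "min-max normalization needs at least two distinct values")
    return (v - v.min()) / (v.max() - v.min())


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic list of n sub-seeds (< 2^31) derived from a base seed."""
    ss = np.random.SeedSequence(int(base_seed))
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint32)]


def _averaged_run(params: ModelParameters, protocol: StimulusProtocol,
                  cond: OpioidCondition, cfg: SimulationConfig,
                  seeds: Sequence[int], label: str) -> ConditionResult:
    peaks, dgs, flags = [], [], []
    for s in seeds:
        c = SimulationConfig(dt=cfg.dt, t_end=cfg.t_end, seed=int(s),
                             record_stride=cfg.record_stride)
        r = simulate(params, protocol, cond, c)
        peaks.append(r.peak_phospho)
        dgs.append(r.final_g_ampa - params.ampar.g_AMPA0)
        flags.append(r.ltp_induced)
    return ConditionResult(
        label=label,
        raw_phospho_camkii=float(np.mean(peaks)),
        raw_phospho_ampar=float(np.mean(dgs)),
        ltp_fraction=float(np.mean(flags)),
    )


def _attach_normalized(conds: list[ConditionResult]) -> None:
    # A flat metric (e.g. every grid point saturating the AMPAR sigmoid)
    # has no min-max scale; report NaN for it rather than failing the sweep.
    for attr, target in (("raw_phospho_camkii", "normalized_camkii"),
                         ("raw_phospho_ampar", "normalized_ampar")):
        vals = [getattr(c, attr) for c in conds]
        try:
            norm = normalize(vals)
        except DegenerateNormalizationError:
            norm = [float("nan")] * len(vals)
        for c, x in zip(conds, norm):
            setattr(c, target, float(x))


def five_conditions(Op: float = 1.0) -> list[tuple[str, OpioidCondition]]:
    return [
        ("normal", OpioidCondition.normal()),
        ("opioid", OpioidCondition.opioid(Op)),
        ("CK=0", OpioidCondition.ck0(Op)),
        ("CMg=0", OpioidCondition.cmg0(Op)),
        ("Icr=0", OpioidCondition.icr0(Op)),
    ]


def run_five_conditions(params: ModelParameters,
                        protocol: StimulusProtocol | None = None,
                        cfg: SimulationConfig | None = None,
                        base_seed: int = 0,
                        n_seeds: int = DEFAULT_N_SEEDS,
                        Op: float = 1.0) -> list[ConditionResult]:
    """Five-condition comparison with min-max normalization across conditions.

    Returns one :class:`ConditionResult` per condition in the order
    normal, opioid, CK=0, CMg=0, Icr=0.
    """
    protocol = protocol or StimulusProtocol()
    cfg = cfg or SimulationConfig()
    seeds = spawn_seeds(base_seed, n_seeds)
    out = [_averaged_run(params, protocol, cond, cfg, seeds, label)
           for label, cond in five_conditions(Op)]
    _attach_normalized(out)
    return out


def _sweep(params: ModelParameters, protocol: StimulusProtocol,
           cfg: SimulationConfig, base_seed: int, n_seeds: int,
           parameter: str, grid: np.ndarray,
           make_run: Callable[[float], tuple[StimulusProtocol, OpioidCondition]],
           ) -> SweepResult:
    seeds = spawn_seeds(base_seed, n_seeds)
    conds = []
    for v in grid:
        proto_v, cond_v = make_run(float(v))
        conds.append(_averaged_run(params, proto_v, cond_v, cfg, seeds,
                                   f"{parameter}={v:g}"))
    _attach_normalized(conds)
    return SweepResult(parameter=parameter, grid=np.asarray(grid, dtype=float),
                       conditions=conds)


def sweep_nmdar_coefficient(params: ModelParameters,
                            protocol: StimulusProtocol | None = None,
                            cfg: SimulationConfig | None = None,
                            grid: Sequence[float] | None = None,
                            base_seed: int = 0,
                            n_seeds: int = DEFAULT_N_SEEDS,
                            Op: float = 1.0) -> SweepResult:
    """Sweep the opioid NMDAR-conductance coefficient (default 0.1 .. 1.0).

    The detected threshold is the smallest grid value whose seed-averaged
    peak Ph.CaMKII exceeds the AMPAR phosphorylation midpoint P_half.
    """
    protocol = protocol or StimulusProtocol()
    cfg = cfg or SimulationConfig()
    if grid is None:
        grid = np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10)

    def make(v):
        return protocol, OpioidCondition(Op=Op, nmdar_coeff=v)

    res = _sweep(params, protocol, cfg, base_seed, n_seeds,
                 "nmdar_coeff", np.asarray(grid, float), make)
    thr = [v for v, c in zip(res.grid, res.conditions)
           if c.raw_phospho_camkii > params.ampar.P_half]
    res.threshold = float(min(thr)) if thr else None
    return res


def sweep_vgcc_coefficient(params: ModelParameters,
                           protocol: StimulusProtocol | None = None,
                           cfg: SimulationConfig | None = None,
                           grid: Sequence[float] | None = None,
                           base_seed: int = 0,
                           n_seeds: int = DEFAULT_N_SEEDS,
                           Op: float = 1.0) -> SweepResult:
    """Sweep the VGCC current multiplier (default 0.0 .. 1.0)."""
    protocol = protocol or StimulusProtocol()
    cfg = cfg or SimulationConfig()
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)

    def make(v):
        return protocol, OpioidCondition(Op=Op, vgcc_coeff=v)

    return _sweep(params, protocol, cfg, base_seed, n_seeds,
                  "vgcc_coeff", np.asarray(grid, float), make)


def sweep_glutamate_amplitude(params: ModelParameters,
                              protocol: StimulusProtocol | None = None,
                              cfg: SimulationConfig | None = None,
                              grid: Sequence[float] | None = None,
                              base_seed: int = 0,
                              n_seeds: int = DEFAULT_N_SEEDS,
                              Op: float = 1.0) -> SweepResult:
    """Descending glutamate-amplitude sweep (default 0.20 .. 0.13 mM).

    The detected threshold is the largest amplitude at which LTP fails
    (seed-averaged peak Ph.CaMKII at or below P_half).
    """
    protocol = protocol or StimulusProtocol()
    cfg = cfg or SimulationConfig()
    if grid is None:
        grid = np.round(np.arange(0.20, 0.13 - 1e-9, -0.01), 10)

    def make(v):
        return protocol.replace(amplitude=v), OpioidCondition.opioid(Op)

    res = _sweep(params, protocol, cfg, base_seed, n_seeds,
                 "glut_amp", np.asarray(grid, float), make)
    failed = [v for v, c in zip(res.grid, res.conditions)
              if not c.raw_phospho_camkii > params.ampar.P_half]
    res.threshold = float(max(failed)) if failed else None
    return res


def sweep_glutamate_frequency(params: ModelParameters,
                              protocol: StimulusProtocol | None = None,
                              cfg: SimulationConfig | None = None,
                              grid: Sequence[float] | None = None,
                              base_seed: int = 0,
                              n_seeds: int = DEFAULT_N_SEEDS,
                              Op: float = 1.0) -> SweepResult:
    """Descending stimulation-frequency sweep (default 5 .. 0.1 Hz)."""
    protocol = protocol or StimulusProtocol()
    cfg = cfg or SimulationConfig()
    if grid is None:
        grid = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.1])

    def make(v):
        return protocol.replace(frequency=v), OpioidCondition.opioid(Op)

    return _sweep(params, protocol, cfg, base_seed, n_seeds,
                  "glut_freq", np.asarray(grid, float), make)
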