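"""Model parameters for the opioid-modulated CA1 spine model.

The model couples a passive spine membrane, kinetic AMPAR/NMDAR gating,
a voltage-dependent NMDAR conductance, stochastic high-voltage-activated
calcium channels (VGCCs), rapid-buffered spine calcium, and a CaMKII/PP1
phosphorylation cascade.  Internal unit system:

    time ms | voltage mV | current pA | conductance nS | concentration uM
    (synaptic glutamate is expressed in mM)

Constants whose published values are available are used verbatim (e.g.
``g_AMPA0 = 0.4 nS``, ``K_s = 100 /s``, the full cascade rate set).  The
remaining constants (membrane, receptor kinetics, Mg-block shape, VGCC
population, total CaMKII) ship as a single calibrated default set; the
calibration protocol is documented in ``docs/methods.md`` and frozen by the
acceptance tests.  Changing any calibrated default is a breaking change.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .errors import ParameterError

#: Faraday constant (C / mol).
FARADAY = 96487.0
#: Molar gas constant (J / mol / K).
GAS_CONSTANT = 8.314

#: Autophosphorylation ladder coefficients (multipliers on v2 for the
#: P1 -> P2 ... P9 -> P10 transitions of the 10-subunit holoenzyme).
LADDER_COEFFS = (1.0, 1.8, 2.3, 2.7, 2.8, 2.7, 2.3, 1.8, 1.0)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class MembraneParameters:
    """Passive spine membrane (single compartment, no spiking)."""

    tau_post: float = 11.7  # membrane time constant (ms)
    V_rest: float = -70.0   # resting potential (mV)
    R_m: float = 13000.0     # input resistance (MOhm)

    def validate(self) -> None:
        _require(self.tau_post > 0, "tau_post must be > 0")
        _require(self.R_m > 0, "R_m must be > 0")


@dataclass
class AMPARParameters:
    """AMPA receptor: two-state kinetic gate and CaMKII-enhanced conductance.

    The conductance follows a sigmoid of phosphorylated CaMKII bounded in
    (g_AMPA0, 2 g_AMPA0): far below P_half the channel stays at its baseline
    0.4 nS, at P_half it sits at 1.5x baseline, and it saturates at twice
    baseline for full phosphorylation.
    """

    g_AMPA0: float = 0.4      # baseline conductance (nS)
    V_AMPA: float = 0.0       # reversal potential (mV)
    alpha_AMPA: float = 0.47   # opening rate (per mM per ms)
    beta_AMPA: float = 0.15   # closing rate (per ms)
    P_half: float = 40.0      # CaMKII level at half-maximal enhancement (uM)
    k_half: float = 0.4       # sigmoid slope (uM)

    def validate(self) -> None:
        _require(self.g_AMPA0 > 0, "g_AMPA0 must be > 0")
        _require(self.alpha_AMPA > 0, "alpha_AMPA must be > 0")
        _require(self.beta_AMPA > 0, "beta_AMPA must be > 0")
        _require(self.k_half > 0, "k_half must be > 0")


@dataclass
class NMDARParameters:
    """NMDA receptor: kinetics, Mg block, and opioid modulation constants.

    The Mg block is a Woodhull-type expression

        Mg(V) = 1 / (1 + [Mg]_o / K(Op) * exp(-z * delta_eff(Op) * F V / R T))

    Opioids act through a saturating occupancy factor
    ``s(Op) = (op_scale*Op)^op_exp / (1 + (op_scale*Op)^op_exp)`` which
    (i) raises the Mg affinity constant ``K = k0 + mg_k_shift * s``,
    (ii) lowers the effective electrical distance
    ``delta_eff = delta + mg_delta_shift * (1 - s)``, and (iii) adds a
    voltage-independent conductance increment ``cond_sat * s`` (scaled by the
    condition's ``nmdar_coeff``).  All three weaken with Op = 0 so that the
    opioid-free synapse is the control.  ``opioid_form = "printed"`` switches
    to the alternative form in which the same three terms decay as
    ``X / (1 + (0.1 Op)^1.2)``; it is kept for comparison only.
    """

    V_NMDA: float = 0.0       # reversal potential (mV)
    alpha_NMDA: float = 1.8   # opening rate (per mM per ms)
    beta_NMDA: float = 0.15   # closing rate (per ms)
    g_VI: float = 0.037        # voltage-independent conductance (nS)
    tau_g: float = 6.0       # g_VD relaxation time constant (ms)
    k_slope: float = 0.10     # gain of g_VD_inf per mV (nS/mV)
    V0: float = -48.0         # offset potential for g_VD_inf (mV)
    Mg_out: float = 1.0       # external Mg2+ concentration (mM)
    k0: float = 115.0          # Mg affinity offset (mM)
    z: float = 2.0            # Mg valence
    delta: float = 0.8        # electrical distance of the block site
    T: float = 308.0          # temperature (K)
    # Opioid-mechanism constants.
    op_scale: float = 10.0      # occupancy scale (per uM of opioid)
    op_exp: float = 1.2         # occupancy Hill-like exponent
    mg_k_shift: float = 15.58   # Mg affinity increase at opioid saturation (mM)
    mg_delta_shift: float = 0.1 # electrical-distance decrease at saturation
    cond_sat: float = 0.15      # conductance increment at saturation (nS)
    opioid_form: str = "saturating"  # "saturating" (default) or "printed"

    def validate(self) -> None:
        _require(self.tau_g > 0, "tau_g must be > 0")
        _require(self.Mg_out >= 0, "Mg_out must be >= 0")
        _require(0 <= self.delta <= 1, "delta must lie in [0, 1]")
        _require(self.alpha_NMDA > 0, "alpha_NMDA must be > 0")
        _require(self.beta_NMDA > 0, "beta_NMDA must be > 0")
        _require(self.k0 > 0, "k0 must be > 0")
        _require(self.T > 0, "T must be > 0")
        _require(self.op_scale >= 0, "op_scale must be >= 0")
        _require(self.op_exp > 0, "op_exp must be > 0")
        _require(self.opioid_form in ("saturating", "printed"),
                 "opioid_form must be 'saturating' or 'printed'")


@dataclass
class VGCCParameters:
    """High-voltage-activated calcium channels with binomial gating.

    Each integration step draws the number of open channels from
    ``Binomial(N, P_open(V))`` with a logistic ``P_open``.  The half-
    activation voltage is high enough that ordinary EPSPs leave the
    channels shut; only the opioid-condition plateau recruits them.
    """

    g_R: float = 0.015     # single-channel conductance (nS; 15 pS)
    V_R: float = 27.4      # reversal potential (mV)
    N: int = 4             # channel count
    Vh_open: float = -9.0   # half-activation voltage (mV)
    k_open: float = 2.7    # activation slope (mV)

    def validate(self) -> None:
        _require(self.N >= 0, "N must be >= 0")
        _require(self.g_R >= 0, "g_R must be >= 0")
        _require(self.k_open > 0, "k_open must be > 0")


@dataclass
class CalciumParameters:
    """Spine calcium balance with rapid endogenous buffering and a linear pump."""

    eta: float = 0.012     # calcium fraction of the AMPAR current
    gamma: float = 0.06    # calcium fraction of the NMDAR current
    Z_ca: float = 2.0      # calcium valence
    V_spine: float = 0.9048  # spine volume (um^3)
    b_t: float = 200.0     # total endogenous buffer (uM)
    K_endo: float = 10.0   # buffer affinity (uM)
    K_s: float = 100.0     # pump rate (per s)
    c_rest: float = 0.1    # resting calcium (uM)

    def validate(self) -> None:
        _require(self.V_spine > 0, "V_spine must be > 0")
        for name in ("eta", "gamma", "Z_ca", "b_t", "K_endo", "K_s", "c_rest"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")

    @property
    def current_to_flux(self) -> float:
        """Conversion factor from pA to uM/ms of free-calcium influx.

        1 pA = 1e-12 C/s; dividing by (Z_ca * F * V_spine) with the volume in
        litres (1 um^3 = 1e-15 L) gives mol/L/s; 1e6 converts to uM/s and
        1e-3 to uM/ms.
        """
        return 1e-12 / (self.Z_ca * FARADAY * self.V_spine * 1e-15) * 1e6 * 1e-3


@dataclass
class CascadeParameters:
    """CaMKII phosphorylation ladder and PP1 / inhibitor-1 regulation.

    Rates are expressed per second (the paper's convention); the engine
    converts to per-ms in exactly one place.
    """

    e_p0: float = 0.1      # total PP1 (uM)
    I_0: float = 0.1       # free inhibitor-1 (uM)
    k3: float = 1.0        # PP1-I1P association rate (per uM per s)
    k4: float = 1e-3       # PP1-I1P dissociation rate (per s)
    v_CaN: float = 2.0     # I1P dephosphorylation rate by calcineurin (per s)
    v_PKA: float = 0.45    # I1 phosphorylation rate by PKA (uM/s)
    K_H2: float = 0.7      # CaN calcium Hill constant (uM)
    k1: float = 0.5        # PP1-dependent regulation rate (per s)
    K_H1: float = 4.0      # CaMKII calcium Hill constant (uM)
    K_M: float = 20.0      # Michaelis constant (uM)
    k2: float = 10.0       # catalytic constant (per s)
    camkii_total: float = 100.0  # total CaMKII subunit concentration (uM)

    def validate(self) -> None:
        for f_ in dataclasses.fields(self):
            _require(getattr(self, f_.name) > 0, f"{f_.name} must be > 0")


@dataclass
class OpioidCondition:
    """Opioid concentration plus the mechanism toggles of the comparison runs.

    The five canonical conditions are built by :meth:`normal`,
    :meth:`opioid` and the three knockouts ``ck0`` (no conductance effect),
    ``cmg0`` (no Mg-block effect) and ``icr0`` (no VGCC current).
    """

    Op: float = 0.0                    # opioid concentration (uM)
    conductance_effect_on: bool = True  # "CK" mechanism
    mg_effect_on: bool = True           # "CMg" mechanism
    vgcc_on: bool = True                # "Icr" mechanism
    nmdar_coeff: float = 1.0           # multiplier on the opioid conductance term
    vgcc_coeff: float = 1.0            # multiplier on the VGCC current

    def validate(self) -> None:
        _require(self.Op >= 0, "Op must be >= 0")
        _require(self.nmdar_coeff >= 0, "nmdar_coeff must be >= 0")
        _require(self.vgcc_coeff >= 0, "vgcc_coeff must be >= 0")

    @classmethod
    def normal(cls) -> "OpioidCondition":
        return cls(Op=0.0)

    @classmethod
    def opioid(cls, Op: float = 1.0) -> "OpioidCondition":
        return cls(Op=Op)

    @classmethod
    def ck0(cls, Op: float = 1.0) -> "OpioidCondition":
        return cls(Op=Op, conductance_effect_on=False)

    @classmethod
    def cmg0(cls, Op: float = 1.0) -> "OpioidCondition":
        return cls(Op=Op, mg_effect_on=False)

    @classmethod
    def icr0(cls, Op: float = 1.0) -> "OpioidCondition":
        return cls(Op=Op, vgcc_on=False)


@dataclass
class ModelParameters:
    """Complete parameter set of the spine model."""

    membrane: MembraneParameters = field(default_factory=MembraneParameters)
    ampar: AMPARParameters = field(default_factory=AMPARParameters)
    nmdar: NMDARParameters = field(default_factory=NMDARParameters)
    vgcc: VGCCParameters = field(default_factory=VGCCParameters)
    calcium: CalciumParameters = field(default_factory=CalciumParameters)
    cascade: CascadeParameters = field(default_factory=CascadeParameters)

    def validate(self) -> None:
        for f_ in dataclasses.fields(self):
            getattr(self, f_.name).validate()
        _require(self.cascade.camkii_total > self.ampar.P_half,
                 "camkii_total must exceed the AMPAR sigmoid midpoint P_half "
                 "(otherwise LTP is unreachable)")

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParameters":
        """Build parameters from a (possibly partial) nested mapping.

        Missing sections/fields keep their defaults; unknown keys raise
        :class:`ParameterError`.
        """
        base = cls()
        sections = {f_.name: f_ for f_ in dataclasses.fields(cls)}
        for sec_name, sec_val in d.items():
            if sec_name not in sections:
                raise ParameterError(f"unknown parameter section {sec_name!r}")
            sub = getattr(base, sec_name)
            known = {f_.name for f_ in dataclasses.fields(sub)}
            for key, val in (sec_val or {}).items():
                if key not in known:
                    raise ParameterError(
                        f"unknown parameter {key!r} in section {sec_name!r}")
                setattr(sub, key, int(val) if key == "N" else
                        (val if isinstance(val, str) else float(val)))
        base.validate()
        return base

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d.get("model", d))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump({"model": self.to_dict()}, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)
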