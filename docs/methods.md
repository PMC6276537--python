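# Methods

## Scope and state

The package simulates calcium-dependent plasticity in one CA1 dendritic
spine driven by a periodic glutamate signal. The 18-dimensional state
couples five biophysical variables (membrane potential V, AMPAR and NMDAR
gating fractions, the voltage-dependent NMDAR conductance g_VD, free spine
calcium c) to thirteen biochemical ones (the CaMKII phosphorylation ladder
P0..P10, active PP1, and free phosphorylated inhibitor-1). The internal
unit system is ms / mV / pA / nS / μM (glutamate in mM); one conversion
layer (`CalciumParameters.current_to_flux`, and the per-ms scaling of the
cascade rates in `kernel.pack_params`) bridges coulombs, litres and
per-second rate constants.

Assumptions worth stating plainly: the spine is a single passive
compartment (no spiking, no dendrite); glutamate is a deterministic
rectangular pulse train (no vesicle stochasticity, no short-term
plasticity); receptor gating is a single two-state kinetic scheme; calcium
buffering is the instantaneous rapid-buffer approximation; the pump is
linear and symmetric about rest; VGCC gating has no intrinsic kinetics
beyond the per-step binomial draw; and the PP1/I1P subsystem starts at its
resting equilibrium, where the phosphatase is almost completely inhibited —
over a 10 s simulation dephosphorylation is therefore negligible and the
switch is effectively one-way.

## Opioid mechanism

Opioid concentration Op enters through a saturating occupancy factor

    s(Op) = (op_scale·Op)^1.2 / (1 + (op_scale·Op)^1.2),  op_scale = 10 /μM,

which (i) raises the Mg-affinity constant of the Woodhull block,
K = k0 + 15.58·s; (ii) lowers the effective electrical distance,
δ_eff = δ + 0.1·(1 − s); and (iii) adds a voltage-independent NMDAR
conductance increment 0.15·s (nS), scaled by the condition's
`nmdar_coeff`. All three terms vanish at Op = 0, so the opioid-free run is
the control, and all three monotonically weaken the Mg block / strengthen
the conductance as Op grows — the direction the modelled biology demands.
An alternative parameterization in which the same three terms decay as
X/(1 + (0.1·Op)^1.2) is retained behind
`NMDARParameters.opioid_form = "printed"` for comparison; it is not used by
any shipped experiment.

The occupancy scale deserves a note: with a half-effect at 10 μM the 1 μM
standard dose would modulate the receptor by only ~6%, which produces no
discernible contrast between conditions in this model. The shipped
half-effect concentration of 0.1 μM puts the standard dose at ~94%
occupancy and is treated as a calibrated constant like the others below.

## Calibrated defaults

Published constants are used verbatim: g_AMPA0 = 0.4 nS, P_half = 40 μM,
k_half = 0.4 μM, η = 0.012, γ = 0.06, z_Ca = 2, V_spine = 0.9048 μm³,
b_t = 200 μM, K_endo = 10 μM, K_s = 100 /s, c_rest = 100 nM, g_R = 15 pS,
V_R = 27.4 mV, e_p0 = 0.1 μM, I_0 = 0.1 μM, k3 = 1 /μM/s, k4 = 1e-3 /s,
v_CaN = 2 /s, v_PKA = 0.45 μM/s, K_H2 = 0.7 μM, k1 = 0.5 /s, K_H1 = 4 μM,
K_M = 20 μM, k2 = 10 /s, the ladder coefficients
(1, 1, 1.8, 2.3, 2.7, 2.8, 2.7, 2.3, 1.8, 1) and F = 96487 C/mol.

The remaining constants have no published values and ship as one
calibrated, version-pinned set (changing any of them is a breaking change):

| constant | value | role |
|---|---|---|
| τ_post | 11.7 ms | EPSP integration window |
| V_rest | −70 mV | resting potential |
| R_m | 13 GΩ | input resistance of the isolated spine head |
| α_AMPA, β_AMPA | 0.47 /mM/ms, 0.15 /ms | AMPAR gating |
| V_AMPA, V_NMDA | 0 mV | reversal potentials |
| α_NMDA, β_NMDA | 1.8 /mM/ms, 0.15 /ms | NMDAR gating |
| g_VI | 0.037 nS | voltage-independent NMDAR conductance |
| k, V₀, τ_g | 0.10 nS/mV, −48 mV, 6 ms | g_VD regeneration |
| [Mg]ₒ, k0, z, δ, T | 1 mM, 115 mM, 2, 0.8, 308 K | Mg block shape |
| N, V_h, k_open | 4, −9 mV, 2.7 mV | VGCC population and activation |
| op_scale, op_exp | 10 /μM, 1.2 | opioid occupancy |
| CaMKII_total | 100 μM | holoenzyme subunit pool (> P_half) |

The calibration protocol (run once; its outcomes are frozen as the
acceptance tests): under the standard stimulus the defaults must yield
(i) no phosphorylation and constant g_AMPA without opioid; (ii) threshold
crossing and g_AMPA growth at 1 μM opioid; (iii) the five-condition
knockout pattern — conductance knockout silent, Mg knockout nearly
inconsequential, VGCC knockout attenuating; (iv) the conductance-coefficient
switch between 0.2 and 0.3; (v) amplitude-supported LTP down to 0.15 mM
collapsing at 0.14 mM; (vi) a graded frequency decline; and (vii) strict
rest quiescence. The set was found by randomized search over the table
above, rounded, and re-verified; every listed contrast is stable to < 1 μM
of peak Ph.CaMKII across independent VGCC noise seeds.

Two intentional consequences of this operating point: the Mg block is
weaker than in a textbook synapse (k0 = 115 mM ≫ the ~3.6 mM of classical
fits), which keeps the Mg-relief pathway subordinate to the conductance
pathway as the knockout pattern requires; and R_m is high, making the spine
electrically compact enough that a ~0.2 nS NMDAR conductance sustains a
regenerative depolarization plateau. Both are phenomenological choices
pinned by the calibration targets, not measurements.

### How the model expresses the experiments

Each pulse of the train triggers an AMPAR EPSP; whether the EPSP ignites
the regenerative NMDAR loop (g_VD growth + Mg relief + conductance
increment) is nearly all-or-none per pulse. An ignited pulse produces a
brief (~15 ms) plateau near −10 mV, which is the only voltage range where
the high-voltage VGCCs open. NMDAR calcium alone raises the spine to a few
μM per plateau; the VGCC draw multiplies that several-fold. Peak
phosphorylated CaMKII over 10 s then reflects the cumulative number of
ignited pulses × per-pulse calcium dose. This is why the conductance
coefficient and the amplitude act as switches (they gate ignition), the
frequency acts gradually (it counts pulses), and the VGCC coefficient acts
gradually (it scales the dose).

## Numerics

- Forward Euler, dt = 0.05 ms, horizon 10 s (2×10⁵ steps), initial state
  at rest with the PP1/I1P analytic equilibrium.
- Per-step order: stimulus → conductances and Mg factor → currents
  (including the binomial VGCC draw) → membrane/gating/calcium derivatives
  → cascade derivatives → Euler update → g_AMPA refresh from the updated
  ladder (a one-step lag, negligible at this dt).
- The ladder update reads a frozen copy of the previous-step rungs, so the
  telescoping fluxes cancel exactly and ΣPᵢ is conserved to float
  round-off even under Euler.
- After each step, gates are clamped to [0,1], concentrations to ≥ 0 and
  PP1 to [0, e_p0], with a breach counter; a run clamping in more than
  1e-4 of its steps raises `StateCorruptionError`. With the shipped
  defaults no standard run clamps at all. Non-finite states raise
  `IntegrationError` naming the variable and time.
- Randomness: the engine pre-draws one uniform variate per step from
  `RandomState(seed)`; the binomial open-channel count is obtained by
  inverse-CDF lookup. Runs are bit-reproducible for a fixed seed, and the
  numba-compiled loop and its pure-Python twin consume identical streams
  (they agree to ~1e-15, the residue of FMA contraction in compiled code).
- Self-convergence: halving dt from 0.05 to 0.025 ms moves V by < 0.1 mV
  over a 1 s opioid run; dt = 1 ms deviates by > 1 mV and is flagged by
  `convergence_check`. The deterministic sub-model (VGCCs off) tracks an
  adaptive LSODA integration (rtol 1e-8, integrated piecewise between pulse
  edges) within 1% of each trace's dynamic range.

## Experiments and their statistics

`run_five_conditions` runs {normal, opioid 1 μM, CK=0, CMg=0, Icr=0},
averages each condition's peak Ph.CaMKII and AMPAR-conductance gain
(final g_AMPA − g_AMPA0 — the model's only AMPAR-phosphorylation
observable) over a seed list (default 5 seeds derived from one base seed
via `SeedSequence`), then min-max normalizes across conditions. Sweeps do
the same per grid point; detected thresholds are reported as grid values,
not interpolated. With the shipped defaults both the opioid and CMg=0
conditions exhaust the CaMKII pool within 10 s, so their peaks tie at
100 μM; ordering assertions therefore treat "opioid maximal" as ≥ with a
tie tolerance while requiring strict separation from Icr=0 and the silent
conditions. A sweep metric that is constant across the grid (e.g. the
saturated AMPAR gain in the VGCC sweep) has no min-max scale and is
reported as NaN rather than an error.

Problem sizes: the shipped tests and the acceptance script use full 10 s
runs; the five-condition comparison is 25 simulations, the coefficient
sweep 50, the amplitude sweep 40 (all 5-seed averages). Unit tests that
only exercise dynamics use 0.3–2 s horizons.

## What the tests do and do not show

The suite demonstrates that the implemented equations have the stated
fixed points, bounds, conservation laws and limits; that the integrator
converges and matches an independent adaptive solver on the deterministic
sub-model; and that the calibrated operating point reproduces the full
qualitative and threshold structure described above, robustly across VGCC
noise. It does not validate the model against electrophysiological
recordings: the stimulus is an idealized pulse train standing in for
opioid-disinhibited presynaptic drive, several constants are calibrated
rather than measured, and the Mg-block/conductance split is only
constrained by the knockout pattern, not by dose-response data. Conclusions
about real synapses inherit those caveats.

## Known limitations

- The CaMKII switch here is effectively irreversible on the simulated
  timescale (PP1 starts inhibited); depotentiation and late-phase dynamics
  are out of scope.
- VGCC noise is binomial per Euler step, so its spectral content depends
  on dt; channel kinetics (activation/deactivation times) are not modelled.
- The printed-form opioid parameterization is provided for comparison but
  uncalibrated; with the shipped constants its net Mg-block direction is
  dominated by the electrical-distance term.
- Normalized readouts compress near saturation: conditions that fully
  exhaust the CaMKII pool are indistinguishable in the bar-plot metric
  even when their calcium histories differ.
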