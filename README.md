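# opioidltp

Simulator of opioid-induced *pathological* long-term potentiation (LTP) in a
dendritic spine of a hippocampal CA1 pyramidal neuron.

Opioids remodel glutamatergic transmission: they weaken the voltage-dependent
Mg²⁺ block of NMDA receptors, enhance NMDAR conductance, and (through the
resulting depolarization) recruit high-voltage-activated calcium channels
(VGCCs). The extra calcium can drive the CaMKII autophosphorylation switch
and phosphorylate AMPA receptors — inducing LTP under a stimulus that leaves
a drug-free synapse untouched. That "false" LTP is a candidate substrate for
addiction memory. This package implements a biophysical model of the process
and the experiments that dissect which mechanism matters.

## Model

A single spine compartment with state
(V, m_AMPA, m_NMDA, g_VD, Ca²⁺, P₀…P₁₀, PP1, I1P):

- **Membrane** — passive: τ dV/dt = −(V − V_rest) + R_m·I_syn with
  I_syn = −(I_AMPA + I_NMDA).
- **Receptors** — two-state kinetic gates dm/dt = α·[glu]·(1−m) − β·m.
  I_AMPA = g_AMPA·m·(V − V_AMPA); I_NMDA = g_NMDA·m·Mg(V)·(V − V_NMDA).
- **Mg²⁺ block** — Woodhull form
  Mg(V) = 1/(1 + [Mg]ₒ/K(Op)·exp(−zδ_eff(Op)FV/RT)); opioid occupancy
  s(Op) raises the affinity constant K and lowers the electrical distance
  δ_eff, relieving the block.
- **NMDAR conductance** — g_NMDA = g_VI + 0.15·s(Op)·coeff + g_VD, with
  g_VD relaxing toward k·(V − V₀) (floored at 0): a regenerative
  depolarization loop.
- **VGCCs** — N channels, logistic open probability, one binomial draw per
  time step; current g_R·n_open·(V − V_R) feeds calcium only.
- **Calcium** — rapid-buffer approximation
  dc/dt = [−(ηI_AMPA + γI_NMDA + I_R)/(z_Ca F V_spine) − K_s(c − c_rest)]
  / (1 + θ(c)), θ = b_t·K_endo/(K_endo + c)².
- **CaMKII/PP1 switch** — an 11-state phosphorylation ladder P₀…P₁₀ with
  calcium-driven initiation (v₁ ∝ Hill⁸), autophosphorylation (v₂, Hill⁴),
  and PP1-mediated dephosphorylation (v₃); PP1 is inactivated by
  phosphorylated inhibitor-1 (PKA source, calcineurin sink).
  **Ph.CaMKII = Σᵢ₌₁¹⁰ Pᵢ**; AMPAR conductance follows
  g_AMPA = g₀·(1 + σ((Ph.CaMKII − P_half)/k_half)), bounded in (0.4, 0.8) nS.

LTP is operationalized as peak Ph.CaMKII exceeding P_half = 40 μM.
Integration is fixed-step forward Euler (0.05 ms, 10 s horizon), seeded and
bit-reproducible. Constants without published values ship as a calibrated,
version-pinned default set (see `docs/methods.md`).

## Worked example

```bash
opioidltp simulate --op 1.0 --seed 42 --out results/
```

```json
{
  "peak_phospho_camkii_uM": 99.999963457772,
  "final_phospho_camkii_uM": 99.99995839867312,
  "final_g_ampa_nS": 0.8,
  "ltp_induced": true,
  "n_invariant_breaches": 0
}
```

With 1 μM opioid the 5 Hz / 0.2 mM glutamate train drives nearly the entire
100 μM CaMKII pool into the phosphorylated state and doubles the AMPAR
conductance (0.4 → 0.8 nS): full pathological LTP. The same command with
`--op 0` leaves Ph.CaMKII below 2 μM and g_AMPA at 0.4 nS.

The mechanism dissection (`opioidltp compare-conditions --seeds 5`):

```text
 label  raw_phospho_camkii  raw_phospho_ampar  ltp_fraction  normalized_camkii  normalized_ampar
normal            1.775622                0.0           0.0           0.000000               0.0
opioid           99.999964                0.4           1.0           1.000000               1.0
  CK=0            3.231026                0.0           0.0           0.014817               0.0
 CMg=0           99.999959                0.4           1.0           1.000000               1.0
 Icr=0           65.820245                0.4           1.0           0.652024               1.0
```

Reading the knockouts: removing the opioid's NMDAR-conductance boost
(`CK=0`) abolishes LTP entirely; removing its Mg-block relief (`CMg=0`)
barely matters; removing the VGCC current (`Icr=0`) attenuates LTP without
blocking it. Conductance enhancement is the trigger, VGCC calcium sets the
magnitude.

Sweeps (`opioidltp sweep --param nmdar_coeff|vgcc_coeff|glut_amp|glut_freq`)
reproduce the model's threshold structure: the conductance coefficient acts
as a none-or-all switch (silent at 0.2, full LTP from 0.3), the glutamate
amplitude supports LTP down to 0.15 mM and collapses at 0.14 mM, and the
stimulation frequency grades LTP smoothly from 5 Hz down to quiescence at
0.1 Hz.

## Layout

| module | contents |
|---|---|
| `opioidltp.params` | parameter dataclasses, calibrated defaults, YAML I/O |
| `opioidltp.stimulus` | glutamate pulse train |
| `opioidltp.biophysics` | membrane / receptor / channel / calcium terms |
| `opioidltp.cascade` | CaMKII ladder and PP1–inhibitor-1 dynamics |
| `opioidltp.kernel` | forward-Euler loop (numba-compiled, Python twin) |
| `opioidltp.engine` | `simulate`, result container, convergence check |
| `opioidltp.experiments` | five-condition comparison and the four sweeps |
| `opioidltp.cli` | `opioidltp` command-line interface |
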