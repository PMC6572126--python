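# bindkit

Characterizing how a small-molecule inhibitor acts on an enzyme is a stack of
small, standard analyses — an IC50 from a dose–response curve, an inhibition
mode and Ki from double-reciprocal kinetics, a reversibility call from
velocity-vs-enzyme plots, binding constants from fluorescence-quenching
titrations, a driving-force assignment from van't Hoff thermodynamics, and a
conformational readout from synchronous-fluorescence shifts. Each step is
simple; chaining them reproducibly, with validated inputs and recoverable
ground truth, is where bench scripts usually fall apart. bindkit packages the
whole chain for enzymologists and binding-spectroscopy users (the defaults
emulate a xanthine oxidase / chalcone-inhibitor study), together with a
synthetic-assay generator so that every fitted constant can be verified by
closed-loop parameter recovery.

## The models

**Inhibition kinetics.** Initial velocities over a substrate × inhibitor grid
follow Michaelis–Menten kinetics; for a competitive inhibitor the
Lineweaver–Burk (double-reciprocal) form is

```
1/v = (Km/Vmax)(1 + [I]/Ki)(1/[S]) + 1/Vmax
```

so 1/Vmax (the vertical intercept) is unchanged by [I] while the apparent
Michaelis constant rises as `Km_app = Km [I]/Ki + Km`; the secondary plot of
Km_app against [I] yields Ki = intercept/slope. The mode classifier reads the
movement of Km_app and Vmax_app across inhibitor levels (competitive:
Vmax constant, Km_app rising; noncompetitive: Km constant, Vmax falling;
uncompetitive: both falling at constant ratio; mixed otherwise). IC50 comes
from a fixed-asymptote logistic, `%inh = 100/(1 + (IC50/[I])^h)`.
Reversibility is diagnosed from velocity-vs-[E] lines per inhibitor level:
parallel lines with [I]-shifted intercepts indicate irreversible titration of
active enzyme; an origin-passing fan of decreasing slopes indicates
reversible binding.

**Fluorescence quenching.** After inner-filter correction
`F_c = F_m·e^((A1+A2)/2)`, three linear fits run per temperature:
Stern–Volmer `F0/F = 1 + K_SV[Q]` (with `K_q = K_SV/τ0`, τ0 = 10⁻⁸ s, judged
against the diffusion limit 2.0×10¹⁰ L mol⁻¹ s⁻¹ to call static vs dynamic
quenching); modified Stern–Volmer `F0/(F0−F) = 1/(f_a·K_a·[Q]) + 1/f_a`; and
the double-log plot `lg((F0−F)/F) = lg K_b + n·lg[Q]` for the binding-site
count n.

**Thermodynamics.** Association constants across temperatures are fit to
`lg Ka = −ΔH/(2.303RT) + ΔS/(2.303R)`; `ΔG = ΔH − TΔS` gives spontaneity and
the (ΔH, ΔS) sign pattern the dominant force (both positive → hydrophobic;
both negative → H-bond/van der Waals; ΔH ≈ 0, ΔS > 0 → electrostatic).

## Worked example

Generate a noiseless synthetic bundle and run every stage:

```bash
bindkit simulate all --out demo --seed 1   # then set noise_sd_rel: 0.0 in demo/config.yaml
bindkit simulate all --out demo --config demo/config.yaml
bindkit run --data demo --out demo/report.json
```

which prints

```
bindkit pipeline report
=======================
ic50            IC50 = 2.93e-06 mol/L (hill 1.00)
inhibition      mode = competitive, Km = 5e-05 mol/L, Vmax = 1, Ki = 4.6e-08 mol/L
reversibility   verdict = irreversible (slope CV 0.000)
quenching       T=298K  K_SV=1.66e+04  K_q=1.66e+12 (static)  K_a=1.66e+04  n=1.00
quenching       T=304K  K_SV=3.78e+04  K_q=3.78e+12 (static)  K_a=3.78e+04  n=1.00
quenching       T=310K  K_SV=8.34e+04  K_q=8.34e+12 (static)  K_a=8.34e+04  n=1.00
thermodynamics  dH = 103.45 kJ/mol, dS = 427.94 J/mol/K, force = hydrophobic
synchronous     dλ=15nm (tyrosine): shift -4.00 nm, intensity decreasing
synchronous     dλ=60nm (tryptophan): shift -1.00 nm, intensity decreasing
```

Every number is the generator's ground truth recovered by the analysis: the
IC50 (2.93×10⁻⁶ mol/L) and Ki (0.46×10⁻⁷ mol/L) match the configured
constants, K_q exceeds the diffusion limit by two orders of magnitude (static
quenching, i.e. a ground-state complex), n ≈ 1 indicates a single binding
site, the positive ΔH/ΔS pair classifies the binding as hydrophobically
driven and ΔG = ΔH − TΔS is negative (spontaneous) at all three
temperatures, and both synchronous channels blue-shift — a more hydrophobic
fluorophore environment as ligand accumulates. The same analyses run on real
CSV tables (`bindkit kinetics`, `bindkit quench`, `bindkit thermo`); column
layouts are documented in `bindkit.pipeline.SCHEMAS`, and concentration
headers in µM/nM/mM are converted automatically.

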