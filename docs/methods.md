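# Methods

## Scope and data model

bindkit analyses four bench assays for an enzyme–inhibitor pair: (1) initial
velocities over a substrate × inhibitor grid, (2) percent inhibition vs
inhibitor concentration, (3) fluorescence-quenching titrations at several
temperatures, and (4) synchronous-fluorescence spectra at excitation–emission
offsets Δλ = 15 and 60 nm. Tables travel as pandas DataFrames with canonical
headers (`substrate_M`, `inhibitor_M`, `enzyme_UmL`, `velocity`,
`quencher_M`, `temperature_K`, `F`, `A1`, `A2`, `wavelength_nm`,
`intensity`); all concentrations are mol/L internally (µM/nM/mM headers are
converted on read), velocities are in arbitrary units per minute because only
ratios enter every fitted constant except Vmax, and energies are joules
internally with kJ in reports.

## Estimation procedures

**Double-reciprocal kinetics.** Per inhibitor level, ordinary least squares
of 1/v on 1/[S] gives Km_app = slope/intercept and Vmax_app = 1/intercept;
an intercept ≤ 0 is reported as a degenerate fit rather than silently
inverted. The fits are deliberately unweighted — they reproduce the classic
plotted procedure — and a global nonlinear least-squares fit of the
competitive rate law v = Vmax[S]/(Km(1+[I]/Ki)+[S]) is available both as a
cross-check (the two agree to 1e-6 on noiseless data) and as the robust Ki
estimator (`analyze_kinetics(..., estimator="nonlinear")`). The reciprocal
transform amplifies relative noise roughly by Km_app/[S] at strongly
inhibited levels; with Ki ≈ 0.5×10⁻⁷ mol/L and inhibitor up to 0.8×10⁻⁶
mol/L, Km_app reaches ~18×Km, so at 2% measurement noise the secondary-plot
Ki carries order-100% median error while the global nonlinear Ki stays
within a few percent. Practitioners' software fits the rate law directly for
the same reason, and the acceptance metrics for stochastic Ki recovery use
the nonlinear path.

**Mode classification.** "Unchanged" is operationalized as a relative spread
(max−min)/mean ≤ tol with tol = 0.05 by default (no numeric criterion exists
in the plotted tradition; 5% matches typical replicate scatter of plate
assays). Decision order: both constant → none; Vmax constant with strictly
rising Km_app → competitive; Km constant with strictly falling Vmax →
noncompetitive; constant Km/Vmax ratio with both falling → uncompetitive;
otherwise mixed. At zero noise the classifier is confusion-free over all
four generating modes; at 2% noise it often degrades to "mixed" because
Vmax_app at the strongest inhibition level is poorly determined (see above),
which is an honest property of the 5% rule, not a defect of the simulation.

**IC50.** A two-free-parameter logistic with asymptotes pinned at 0 and 100%
(concentration at half-inhibition and a Hill slope), initialized from the
linear interpolation of the 50% crossing. Data that never cross 50% raise an
indeterminate-IC50 error; non-monotonicity beyond 10 percentage points
triggers a warning. Zero-concentration rows are excluded (the model is
defined for [I] > 0 and tends to 0% there).

**Reversibility.** Per inhibitor level, v vs [E] lines are fit by OLS. The
verdict is *irreversible* when the slope coefficient of variation is ≤ 0.05
and the intercept magnitudes grow with [I] (parallel lines, enzyme titrated
away); *reversible* when slopes strictly decrease with [I] and intercepts
are ≈ 0 relative to the velocity scale (origin fan); *indeterminate*
otherwise, including the no-effect case of identical lines.

**Quenching and binding.** Intensities are corrected as
F_c = F_m·e^((A1+A2)/2) whenever absorbances are present (the correction is
skipped and flagged otherwise; it is monotone, F_c ≥ F_m). F0 is the
corrected intensity of the mandatory [Q] = 0 row. Stern–Volmer, modified
Stern–Volmer and double-log fits are unweighted OLS on their respective
transforms; K_q = K_SV/τ0 holds exactly by construction, with τ0 defaulting
to 10⁻⁸ s (typical biomolecule lifetime, overridable). The double-log
intercept is read as lg K_b by default; a convention switch reads it as
n·lg K_b for compatibility with sources that print the equation that way —
the two agree whenever n ≈ 1. Systematic enhancement (F > F0) yields an
indeterminate mechanism with a warning; single unquenched points are dropped
with a warning.

**Thermodynamics.** OLS of lg Ka on 1/T with the decadic factor written as
2.303 exactly, so ΔH = −2.303·R·slope and ΔS = 2.303·R·intercept
(R = 8.314 J mol⁻¹ K⁻¹). Two temperatures give a through-points solution
flagged low-confidence (r undefined); one raises. ΔG = ΔH − TΔS is evaluated
at each input temperature and the identity holds to machine precision in
every result object. Force classification follows the Ross sign convention;
the "ΔH ≈ 0" band for the electrostatic call is |ΔH| < 4 kJ/mol by default
(an order of magnitude below typical binding enthalpies) and configurable.
A binding with ΔH > 0 is labelled by sign (endothermic), whatever the
entropy term does.

**Synchronous shifts.** Peaks are located by 3-point parabolic interpolation
around the discrete maximum, giving sub-grid (≪0.5 nm) precision so that a
1 nm tryptophan shift is resolved on a 0.5 nm grid. The shift is signed
(negative = blue); intensity trend is a monotonicity test on interpolated
peak heights. Δλ = 15 nm is labelled tyrosine and Δλ = 60 nm tryptophan, the
standard channel assignment.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses are validated under: substrate grid
{25, 37.5, 50, 75, 100}×10⁻⁶ mol/L, inhibitor grid {0, 0.2, 0.4,
0.8}×10⁻⁶ mol/L, quencher 0–36.36×10⁻⁶ mol/L in 12 steps, temperatures
{298, 304, 310} K, Km = 50×10⁻⁶ mol/L (mid-grid), Vmax = 1 a.u./min,
Ki = 0.46×10⁻⁷ mol/L, IC50 = 2.93×10⁻⁶ mol/L with Hill slope 1,
ΔH = 103.45 kJ/mol and ΔS = 427.94 J/mol/K (giving Ka(298 K) ≈ 1.66×10⁴
L/mol, rising with temperature). The dose grid (0.5–16×10⁻⁶ mol/L) and the
enzyme grid (0.006–0.030 U/mL around a 0.024 U/mL working concentration) are
invented where the emulated assay family leaves them unstated, chosen to
bracket IC50 and to keep all velocities positive. Noise is multiplicative
Gaussian with relative SD `noise_sd_rel` (default 0.02, a typical
spectrometer/plate CV; no replicate-level scatter is available to fit it
to), clipped at physical bounds; identical config + seed is bit-identical.

The titration simulator uses the pure-static limit F0/F = 1 + Ka(T)[Q], so
the Stern–Volmer slope recovers Ka exactly; the modified Stern–Volmer and
double-log fits are validated against data generated from their own
functional forms (the three transforms are not mutually exact for one
mechanism — in the pure-static 1:1 limit they coincide with f_a = n = 1,
which is what the closed-loop tests assert). Measured intensities are
attenuated by the inverse inner-filter factor with A1 = A2 =
`inner_filter_slope`·[Q] (default 10⁴ AU per mol/L, a typical ligand molar
absorptivity, giving A ≈ 0.36 at the top of the titration), so correction is
load-bearing in the closed loop. The reversibility simulator titrates away
up to 80% of the lowest enzyme level at maximal [I] (irreversible truth) or
scales slopes by 1/(1+[I]/Ki) (reversible truth). Synchronous spectra are
single Gaussians (σ = 8 nm) whose center drifts linearly with [Q]
(defaults: 290 → 286 nm at Δλ = 15; 276 → 275 nm at Δλ = 60); emission
spectra are two Gaussians at 340/405 nm over 300–500 nm. The generator does
not emulate Raman/scatter bands, detector saturation, or pipetting error,
so passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to structured instrumental artifacts.

## Problem sizes and numerical choices

Stochastic validation uses 200 replicate simulations at 2% relative noise on
the default grids — enough for stable medians while keeping the whole suite
in seconds. Nonlinear fits use `scipy.optimize.curve_fit` with tight
(1e-14) tolerances and data-derived initial values; linear fits use
`scipy.stats.linregress`. Mixed inhibition needs a second constant and uses
Ki' = α·Ki with α = 2 by default. Ties and degeneracies raise typed
exceptions (`FitDegenerateError`, `NoInhibitionError`,
`IndeterminateIC50Error`) rather than returning unphysical numbers; the
boundary K_q exactly at the diffusion limit is classified indeterminate.

## Known limitations

Progress-curve (time-course) analysis, tight-binding corrections,
inactivation rate constants, FRET distances, lifetime fitting and
heat-capacity-corrected (nonlinear) van't Hoff analysis are out of scope.
The irreversibility diagnostic and the competitive-mode call are reported
independently and are not reconciled mechanistically — data can support
both, as the parallel-line and double-reciprocal criteria probe different
experiments. Ka values fed to the van't Hoff stage come from the modified
Stern–Volmer fit; at realistic noise they are the least stable constants in
the chain (the accessible-fraction intercept is an extrapolation), so
pipeline-level ΔH/ΔS on noisy data carry wide errors even when each per-T
fit looks acceptable.
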