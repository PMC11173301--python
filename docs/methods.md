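# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic generators do and do not emulate.

## Quenching models

The observable is the ratio F0/F of unquenched to quenched steady-state
tryptophan emission (excitation 280 nm, read at the emission maximum,
~345 nm) versus total ligand concentration in mol/L. Three models are
fitted.

**Classical Stern–Volmer.** Ordinary least squares of F0/F on [Q]. The
intercept is *not* constrained to 1 by default — the data should earn its
intercept, and a drifting intercept is itself diagnostic — but a
`force_unit_intercept` option provides the constrained variant. Derived
quantities are exact arithmetic identities of the slope: `K_q = K_SV/τ`
(τ defaults to the literature tryptophan lifetime of 5 ns and is
configurable) and `K_d = 1/K_SV`, valid under static 1:1 complexation. The
mechanism call is `static` iff `K_q` strictly exceeds the diffusion-limit
threshold (default 10¹⁰ L·mol⁻¹·s⁻¹); at the threshold, dynamic quenching
cannot be excluded.

**Segmented Stern–Volmer.** Points are concentration-ordered; every split
leaving ≥ `min_points_per_segment` (default 3) points per side is scored by
the pooled RSS of two independent OLS lines, ties broken toward the lower
split. The two-segment model must beat the single line in an F-test with 2
extra degrees of freedom at level α (default 0.05), Bonferroni-corrected
over the number of candidate splits because the split is itself selected;
otherwise the result carries an `unimodal` flag and both segments alias the
global fit. The reported breakpoint is the concentration at which the two
fitted lines intersect, clipped into the gap between the boundary
concentrations (geometric mean of the gap if the lines are near-parallel).
On exactly piecewise-linear data the intersection reproduces the joint to
machine precision. Two calibration facts, measured on 1000 seeded
replicates and reflected in the tests: on smooth two-site data (below) the
intersection lands at ~1.45 µM, slightly above the 1 µM stoichiometric
elbow, because the low branch is concave; and on purely linear data with 2%
multiplicative noise the breakpoint false-positive rate is ~6% — above the
nominal corrected level because the noise on F0/F is heteroscedastic (its
standard deviation grows with the ratio). A significance gate at α = 0.05
by construction flags a few percent of linear datasets; users wanting a
hard guarantee should lower α.

**Lehrer (modified Stern–Volmer).** The default `direct` method fits
F/F0 = 1 − f_a·K_SV·[Q]/(1 + K_SV·[Q]) by bounded nonlinear least squares
(f_a ∈ (0,1]); the classical `linearized` double-reciprocal OLS of
F0/(F0−F) on 1/[Q] is retained for comparison and supplies the starting
point of the direct fit (falling back to asymptote/scale heuristics when
the reciprocal transform misbehaves on noisy low-quenching points). The
direct form is the default because reciprocal transforms inflate noise
precisely where quenching is smallest. Points with F ≥ F0 at nonzero
ligand are excluded with a warning, never clamped. Parameter uncertainties
are OLS/NLS standard errors (delta method for the linearized
reparametrization); reported ± values are therefore asymptotic, not
bootstrap.

**Inner-filter correction.** F_corr = F_obs·10^((A_ex+A_em)/2) per point,
from the absorbances at the excitation and emission wavelengths; a
`corrected` flag makes double application an error.

## CD processing and secondary structure

Raw ellipticity in mdeg converts to mean residue ellipticity by the
standard convention [Θ] = θ·MRW/(10·l·c) with MRW defaulting to 117.53
g/mol (the mean residue weight of the receptor construct), l in cm, c in
g/L. The one-line form of this equation is typographically ambiguous in
parts of the literature about whether l and the factor 10 divide or
multiply; the convention used here produces the conventional ~10³–10⁴
deg·cm²·dmol⁻¹ magnitudes for folded proteins, and the conversion refuses
to run twice.

Secondary-structure fractions come from constrained least squares of an
MRE spectrum onto three fixed reference curves (helix, sheet, coil) on the
200–240 nm grid. The basis shipped with the package
(`data/cd_basis_v1.csv`) is **synthetic**: a parametric Gaussian band model
of the canonical far-UV shapes (helix: 208/222 nm double minimum; sheet:
~217 nm minimum; coil: strong negative band below 200 nm), tabulated at
0.5 nm with its generating expressions in the file header. It is not
derived from any measured reference protein set, and absolute fractions
estimated on real spectra with it should be treated as desk-scale
estimates; the `BasisSet` is pluggable so a laboratory basis can be
substituted. Large-reference-set deconvolution (CONTIN/SELCON/CDSSTR
style) is deliberately out of scope.

With only three components, the non-negative sum-to-one problem is solved
*exactly*: all seven support subsets are enumerated and an
equality-constrained normal-equation (KKT) solve is performed on each,
keeping the feasible solution with minimal RSS. This meets the
noiseless-recovery contract (1e-6) that iterative SLSQP-type solvers only
approximate. The estimator is scale-sensitive by design — spectra are not
renormalized, so a mis-scaled spectrum shows up as residual, not as
silently rescaled fractions.

## Thermal unfolding

S(T) = [N(T) + U(T)·K(T)]/(1 + K(T)) with K = exp[−(ΔH_app/R)(1/T −
1/Tm)], T in kelvin internally, linear baselines in °C. ΔH_app is an
apparent van 't Hoff steepness parameter required by any two-state form; it
is introduced by this package (default initialization 300 kJ/mol) and must
not be interpreted thermodynamically, because the unfolding of this
receptor is irreversible — Tm is likewise an *apparent* midpoint.
Initialization is deterministic: Tm from the derivative midpoint, baselines
from OLS on the first/last three points. The fit is flagged
`no_transition` when the derivative prescan finds no transition or the
fitted Tm escapes the data range; genuine non-convergence raises with
diagnostics.

The model-free cross-check (`tm_by_derivative`) boxcar-smooths the trace
(halfwidth 1 point), takes central differences, and refines the extremal
derivative with a local parabola, giving sub-grid resolution on the
3-degree default grid. A trace is called transition-free when the peak
derivative magnitude is below twice the median magnitude — exactly-linear
traces sit at ratio 1, while the broadest transitions resolvable on the
default grid (ΔH_app = 150 kJ/mol) sit at ratio ≳ 2.7; the threshold
2.0 separates them. Sloped baselines comparable in steepness to the
transition itself can defeat this heuristic (known limitation). Derivative
and two-state midpoints agree within 0.1 °C on noiseless default-grid
curves.

Melting analyses default to the fixed wavelengths 210 and 225 nm; the
wavelength is metadata on the curve and a free parameter, and `delta_tm`
refuses to compare midpoints taken at different wavelengths.

## Synthetic generators

Each generator is the documented inverse of one analysis and is
deterministic given its seed; with zero noise, generation followed by
analysis recovers the truth to numerical precision (tested). Defaults are
the study conditions: 1 µM protein; ligand grid 0.1, 0.3, 0.5, 1, 3, 5,
10, 20, 40 µM with a leading zero-ligand point defining F0; CD at 5 µM
protein (≈0.147 g/L for a ~29 kDa domain) in a 0.2 cm cell, 200–240 nm;
melts 15–72 °C in 3-degree steps (20 points). Noise defaults: 1%
multiplicative Gaussian (CV) for fluorescence and melts — detector
shot-like behavior — and 0.2 mdeg additive for CD.

The two-site titration treats the sites as independent (no cooperativity):
site-1 occupancy uses the exact 1:1 mass-balance quadratic, evaluated in
the conjugate form θ₁ = 2L/(s + √(s²−4PL)) to avoid catastrophic
cancellation in the weak-binding limit; the ligand left over after site-1
binding populates site 2 through a free-ligand isotherm; the two quenching
contributions multiply, F = F0(1−q₁θ₁)(1−q₂θ₂). The per-site quench
efficiencies (defaults q₁ = 0.45, q₂ = 0.5) are plausible placeholders —
the true per-residue efficiencies of the two tryptophans are unknown.
Defaults K_d1 = 50 nM, K_d2 = 40 µM place the slope change at the 1:1
point of a 1 µM protein solution.

The band-model emission generator (Gaussian tryptophan band at 345 nm,
tyrosine at 303 nm; synchronous mode as a single tryptophan-tracking band
on the 260–320 nm axis) exists to exercise spectral plumbing
(band reading, blank subtraction) and the consistency between
spectrum-level and table-level quench series. None of the generators
simulate photobleaching, temperature drift, stray light or instrument
response; passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise model, not robustness to every artifact
of real spectra.

## Problem sizes and tolerances

Recovery experiments use 100 seeded replicates (medians reported), chosen
as the package's standard experiment size; all run in seconds. Key
tolerances: I/O round-trips and spectral arithmetic at 1e-12 relative
(floating-point addition/subtraction is not exact, so "exact" inverses are
asserted at this level); noiseless inverse pairs at 1e-6 relative or
better; the occupancy quadratic agrees with an independent bisection
oracle to 1e-10 relative over 1000 random (P, L, K_d) triples. The
breakpoint search is exhaustive, so segmented results are deterministic
given the data; ties in RSS go to the lower concentration.

## Formats

CSV schemas (exact header names, '.' decimal, `# key = value` metadata
comments): `wavelength_nm,intensity` for spectra (CD metadata: `units`,
`mrw`, `conc_g_L`, `path_cm`), `ligand_conc_M,F[,A_ex,A_em]` plus
`protein_conc_M`/`tau_s` metadata for titrations,
`temperature_C,signal[,wavelength_nm]` for melts. Readers reject
out-of-order or duplicated abscissae rather than silently sorting
titrations, and a minimal read-only JCAMP-DX path handles single-block
`XYDATA=(X++(Y..Y))` records with XFACTOR/YFACTOR scaling. Wavelength
grids must match exactly for spectral arithmetic; there is deliberately no
resampling operation (resampling smuggles in smoothing).
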