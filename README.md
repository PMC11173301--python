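# fxrspec

Spectroscopic protein–ligand binding analysis for titration experiments on
the FXR ligand-binding domain (and, generally, any single-tryptophan-ish
protein quenched by a small-molecule ligand): fluorescence-quenching
regression in its classical, segmented and accessible-fraction forms,
circular-dichroism processing, and apparent two-state thermal unfolding —
together with seeded mechanistic generators that produce synthetic datasets
with known ground truth for every analysis.

## The science

**Fluorescence quenching.** Titrating a ligand [Q] against a protein whose
intrinsic tryptophan emission it quenches gives the Stern–Volmer relation

    F0 / F = 1 + K_SV [Q]

The slope `K_SV` (L·mol⁻¹) equals the association constant when quenching is
static (complex formation), so `K_d = 1/K_SV`. The apparent bimolecular rate
`K_q = K_SV/τ` (τ = tryptophan lifetime, 5 ns by default) discriminates the
mechanism: values far above the diffusion limit (~10¹⁰ L·mol⁻¹·s⁻¹) rule
out purely collisional quenching.

Plots with **two linear regimes** — a steep low-concentration branch that
bends near the 1:1 protein:ligand point, then a shallower branch — are
handled by a segmented regression: every admissible split of the
concentration series into two segments (≥ 3 points each) is scored by
pooled residual sum of squares of two independent OLS lines, an F-test
(α = 0.05, Bonferroni-corrected over the candidate splits) gates against
over-fitting a single line, and the breakpoint is reported as the
concentration where the two fitted lines cross.

When only a **fraction f_a of the fluorophores is accessible** to the
quencher, the modified Stern–Volmer (Lehrer) model applies:

    F0 / (F0 − F) = 1/([Q]·K_SV·f_a) + 1/f_a
    equivalently  F = F0 (1 − f_a·K_SV·[Q] / (1 + K_SV·[Q]))

fitted either by the classical double-reciprocal OLS or (default) directly
by nonlinear least squares, which does not inflate noise at low quenching.

**Circular dichroism.** Raw ellipticity θ (mdeg) is converted to mean
residue ellipticity `[Θ] = θ·MRW/(10·l·c)` (deg·cm²·dmol⁻¹; MRW = mean
residue weight, l = path in cm, c in g/L), then unmixed onto a
three-component helix/sheet/coil reference basis under non-negativity and
sum-to-one constraints (solved exactly by support enumeration).

**Thermal unfolding.** Melts S(T) are fitted with the apparent two-state
model `S = (N + U·K)/(1 + K)`, `K = exp[−(ΔH_app/R)(1/T − 1/Tm)]` with
linear baselines N(T), U(T); `Tm` is the unfolding midpoint and ligand
shifts ΔTm = Tm(holo) − Tm(apo) report (de)stabilization. A model-free
derivative midpoint provides the cross-check and the fit's starting value.

All estimators follow the scikit-learn protocol (`fit`/`predict`/
`transform`, fitted attributes with trailing underscores) and compose with
sklearn pipelines; the module-level functions (`stern_volmer_fit`,
`segmented_sv_fit`, `lehrer_fit`, `estimate_secondary_structure`,
`fit_melt_two_state`, …) are thin wrappers operating on the typed
containers (`QuenchTitration`, `CDSpectrum`, `MeltCurve`).

## Worked example

```python
import fxrspec as fx

# two-site quenching titration, 1 uM protein: tight site (Kd 50 nM) plus
# weak site (Kd 40 uM), 1% multiplicative noise
tit = fx.gen_two_site_titration(fx.TwoSiteTruth(noise_cv=0.01), seed=11)
seg = fx.segmented_sv_fit(tit)
print(seg.low.ksv, seg.high.ksv, seg.breakpoint)

lf = fx.lehrer_fit(fx.gen_lehrer_titration(
    fx.LehrerTruth(fa=0.44, ksv=117050.0, noise_cv=0.01), seed=11))

cd = fx.gen_cd_spectrum(fx.CDTruth(fractions=(0.68, 0.16, 0.16),
                                   noise_sd=0.2), seed=11)
sf = fx.estimate_secondary_structure(fx.mdeg_to_mre(cd))

apo  = fx.fit_melt_two_state(fx.gen_melt(fx.MeltTruth(tm_C=51.18, noise_cv=0.02), seed=11))
holo = fx.fit_melt_two_state(fx.gen_melt(fx.MeltTruth(tm_C=53.84, noise_cv=0.02), seed=12))
print(fx.delta_tm(apo, holo))
```

prints (formatted):

```
low-range  Ksv = 608,252 L/mol  (Kq = 1.22e+14 L/mol/s, Kd = 1.64 uM)
high-range Ksv = 16,583 L/mol  (Kd = 60.30 uM)
breakpoint = 1.42 uM
mechanism: static
fa = 0.452 +/- 0.013, Ksv = 110,688 L/mol
helix 68.0%, sheet 16.0%, coil 16.0%
Tm(apo) = 51.19 C, Tm(holo) = 54.27 C, dTm = +3.08 C
```

Reading: the segmented fit finds the slope change at ~1.4 µM — just above
the 1:1 stoichiometric point of the tight site, as expected for a
tight-binding titration; the steep low-range slope gives an apparent rate
`K_q` four orders of magnitude above the diffusion limit, hence static
quenching; the Lehrer fit recovers the generating accessible fraction
(0.44) within its standard error; the CD unmixing returns the generating
68% helix content; and the ligand-bound melt is stabilized by ~3 °C.

## Command line

```sh
fxrspec simulate --kind melt --seed 3 --out melt.csv --param tm_C=53.84
fxrspec fit-melt melt.csv --out melt.json
fxrspec validate examples/demo_pipeline.yaml
fxrspec run --config examples/demo_pipeline.yaml --out demo_out --seed 17
```

`run` executes a config-driven pipeline (generation and/or file input, any
subset of the analyses) and writes per-dataset CSVs plus a versioned JSON
report; identical config + seed reproduces the report byte-for-byte apart
from its timestamp.

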