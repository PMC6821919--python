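# quenchbind

Analysis toolkit for protein–ligand binding studied by fluorescence
quenching titrations, built around the tryptophan emission of serum
albumin titrated with a small-molecule ligand. It is aimed at molecular
biophysicists who need the full quantitative chain from raw emission
spectra to binding constants, thermodynamics and cooperative-site
analysis — with the inner-filter correction applied over the *whole*
spectrum first, because skipping it produces artefacts (a false red shift
of the emission maximum) that masquerade as polarity changes around the
fluorophore.

## What it computes

**Inner-filter correction.** Observed emission is attenuated by the
ligand's own absorption of both the excitation beam and the emitted
light:

    F_corr(λ) = F_obs(λ) · 10^((A_ex + A_em(λ))/2)

Applied point-by-point over the spectrum (and, for synchronous spectra,
with A at λ_exc and λ_exc + Δλ). When the ligand band (peak 326 nm,
ε = 18 700 M⁻¹cm⁻¹) overlaps the blue flank of the tryptophan emission
band (340 nm), uncorrected spectra show an apparent red shift that the
correction removes.

**Stern–Volmer and mechanism.** F₀/F = 1 + K_SV[L] = 1 + k_q τ₀[L],
fitted with the intercept fixed at 1, from either the intensity at 340 nm
or the 305–400 nm band area. k_q = K_SV/τ₀ far above the collisional
ceiling of 10¹⁰ M⁻¹s⁻¹, together with τ₀/τ ≈ 1 while F₀/F grows,
classifies the quenching as static (ground-state complex).

**Double-log binding fit.** log((F₀−F)/F) regressed on
log([L] − ((F₀−F)/F₀)[P]) gives the binding constant K_a (from the
intercept) and apparent site number n (slope), in a single pass.

**Van't Hoff thermodynamics.** ln K_a against 1/T yields ΔH (slope) and
ΔS (intercept); ΔG = −RT ln K_a per temperature.

**Interaction density function (IDF).** Model-free: equal quench
percentages ΔF = |F_obs − F₀|/F₀·100 across titrations at several protein
concentrations imply equal free ligand, so each horizontal cut through
the ΔF curves gives a mass-conservation line
[L]_total = [L]_free + Σν·[P] whose slope is the binding density Σν. The
(Σν, [L]_free) points feed a Scatchard diagnostic (convex hump ⇒ positive
cooperativity) and a multi-class Hill fit

    Σν = Σ_j n_j (k_j [L]_free)^{w_j} / (1 + (k_j [L]_free)^{w_j})

with the class count selected by corrected AIC.

**Time-resolved fluorescence.** Mono/bi-exponential TCSPC tail fits and
the intensity-weighted mean lifetime τ_avg = Σα_iτ_i²/Σα_iτ_i.

**CD utilities.** Mean residue ellipticity
[θ] = θ/(10·[P]·l·n) and location of the 208/222 nm negative bands.

A ground-truthed synthetic-data generator (`quenchbind.synthetic`)
produces titration spectra with cooperative static quenching and
inner-filter attenuation, TCSPC decays and CD curves, so every stage of
the pipeline can be validated against known parameters.

## Worked example

```python
from quenchbind import (GroundTruth, simulate_titration, build_curve,
                        stern_volmer_fit, match_levels,
                        binding_density_curve, scatchard, hill_fit,
                        vant_hoff_fit)

truth = GroundTruth()                       # 2/4/8 uM protein, 0-32 uM ligand
series = [s.corrected() for s in simulate_titration(truth)]

levels = match_levels(series, levels=20)
bd = binding_density_curve(levels)
print(scatchard(bd).summary())
print(hill_fit(bd, max_classes=3).summary())
```

prints

```
Scatchard diagnostic over 20 points: positive-cooperative

Multi-class Hill fit (affinity-index model)
--------------------------------------------------------
classes selected: 2  (AICc scan: 1: -30.3, 2: -144.4, 3: -137.0)
points: 20   RSS: 8.570e-03
class   n_j     k_j (M^-1)      w_j
    1  1.00  2.358e+05 +/- 4.1e+03    2.672 +/- 0.15
    2  1.00  1.311e+05 +/- 1.6e+03    7.400 +/- 0.3
```

— the pipeline recovers the generator's two cooperative site classes
(true k = 2.3×10⁵ and 1.3×10⁵ M⁻¹) within a few percent; the affinity
indexes carry the piecewise-linear inversion error of the 2 µM titration
ladder. A Van't Hoff run on binding constants measured at 288/298/308 K:

```python
res = vant_hoff_fit({288: 1.72e4, 298: 2.24e4, 308: 2.54e4})
print(res.summary())
```

```
Van't Hoff analysis
------------------------------------------------------------------
dH =    14.43 +/- 2.67 kJ/mol   dS =   131.34 +/- 8.96 J/(mol K)   r^2 = 0.9669

  T (K)   dG=-RTlnKa    dG=dH-TdS      T dS   (kJ/mol)
  288.0       -23.35       -23.40     37.83
  298.0       -24.82       -24.71     39.14
  308.0       -25.97       -26.03     40.45
```

ΔG < 0 at every temperature (spontaneous binding) with the entropic term
T·ΔS dominating ΔH — the signature of hydrophobically driven binding.

## Command line

`quenchbind simulate|correct|quench|thermo|idf|lifetime|cd|report` — thin
wrappers over the library that read the package's delimited text formats
and write JSON reports with a provenance block. See `quenchbind --help`.

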