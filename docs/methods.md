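# Methods

## Observation model and correction order

Fluorescence observed in a right-angle cuvette is attenuated by whatever
absorbs at the excitation and emission wavelengths. The whole-spectrum
correction F_corr(λ) = F_obs(λ)·10^((A_ex + A_em(λ))/2) assumes the
standard half-path geometry (absorber uniformly distributed, effective
path half the cuvette on each leg). Absorbance is linearly interpolated
onto the required wavelengths and never extrapolated; negative
absorbances are rejected. The correction accepts either a measured
total-sample absorbance spectrum or, when only the ligand absorbs
appreciably in the region, a Beer–Lambert spectrum computed from the
ligand concentration, a unit-normalised band shape and
ε = 18 700 M⁻¹cm⁻¹ at 326 nm with a 1 cm path. Both entry points are
exposed because instruments often do not log per-titration-point
absorbance.

Buffer-scatter baselines are subtracted **before** the inner-filter
correction: the correction factor is ≥ 1 everywhere, so correcting first
would amplify the scatter signal that subtraction is meant to remove.
Negative values after subtraction are clamped to zero (fluorescence
cannot be negative) and the clamp count is logged.

Peak location is plain grid argmax with ties broken toward the shortest
wavelength; its resolution is the grid spacing, so all shift statements
are made to ± one grid step. No parabolic refinement is attempted —
sub-grid peak claims would be spurious at the 8–10 nm bandwidths typical
of these measurements.

## Quenching analysis

Quenching curves are built in intensity mode (default read-out 340 nm,
linear interpolation on the grid) or area mode (trapezoidal integral over
305–400 nm, the upper bound chosen to limit contamination by ligand
emission). Curve construction refuses spectra that do not carry the
`corrected` provenance flag: every ratio-based quantity downstream is
biased if the inner filter is left in.

The Stern–Volmer fit fixes the intercept at 1 by default because the law
F₀/F = 1 + K_SV[L] has no free intercept; the slope is the exact
least-squares solution through the origin on (F₀/F − 1). A free-intercept
ordinary regression is available as a diagnostic for curvature or offset
problems. k_q = K_SV/τ₀ uses a caller-supplied τ₀ (the same value at all
temperatures — lifetimes vary little over 288–308 K relative to the
precision of K_SV).

Mechanism classification makes the field's qualitative rules explicit
and configurable: *static* requires k_q > 10¹⁰ M⁻¹s⁻¹ and the maximum
excursion of τ₀/τ below 25% of the maximum excursion of F₀/F; *dynamic*
requires |τ₀/τ − F₀/F| within 5% relative at every point; anything else
is *mixed*. The two thresholds are parameters (`flat_frac`,
`equiv_tol`).

The double-log binding fit implements the one-pass form: the bound-ligand
correction term uses (F₀−F)/F₀ directly, with no self-consistent
iteration, because that is how the regression is conventionally run.
Points whose log arguments are non-positive (no measurable quench, or
bound ligand exceeding total) are dropped with a warning; at least four
usable points are required. The Ka standard error is propagated from the
slope/intercept covariance by the delta method.

## Van't Hoff

Unweighted OLS of ln Ka on 1/T by default (three temperatures are typical
and weights from two-significant-figure Ka values add little); optional
1/SE² weighting. Standard errors come from the regression covariance with
the exact small-n formula (the three-point case has one residual degree
of freedom). ΔG is reported both as −RT ln Ka at each temperature and as
ΔH − TΔS from the fitted line; the two differ by the per-temperature
regression residual, and showing both makes the residual visible instead
of hiding it in one column. R = 8.314 J mol⁻¹ K⁻¹, temperatures in K,
ΔH in kJ/mol, ΔS in J mol⁻¹ K⁻¹.

## Interaction density function

Quench percentages use the area-mode signal by default (configurable to
340 nm intensity). Each titration's ΔF is checked for monotone growth in
total ligand: downward excursions up to 2 percentage points (noise) are
flattened by a running maximum before inversion; larger violations raise
an error naming the offending series. Inversion of ΔF against
log₁₀[L]_total uses monotone piecewise-linear interpolation — titration
ladders are closer to geometric in effect, so interpolating in the log
coordinate keeps the inversion error roughly uniform across the ladder.
Strict monotonicity is enforced with a 1e-9 jitter before interpolation.

The level grid defaults to 20 evenly spaced ΔF values spanning the
intersection of all series' ΔF ranges, inset by a 2% margin at each end;
the count and placement are configurable since there is no canonical
choice. Each level's (P_total, L_total) points are regressed by OLS;
levels with a negative free-ligand intercept (unphysical) or r² < 0.95
are flagged and excluded from the binding-density curve, with a log
entry.

The Scatchard verdict works on the ordered sequence Σν/[L]_free:
*positive-cooperative* when it rises to an interior maximum and then
falls, *non-cooperative* when monotone decreasing, *indeterminate*
otherwise. A relative tolerance of 2% of the largest transformed value
absorbs interpolation wiggles; the tolerance is asymmetric in the safe
direction — a sequence that is decreasing within tolerance can never be
called cooperative, so Langmuir (w = 1) data are never misclassified.

The Hill fit runs in log-parameter space (log k_j, log w_j; log n_j too
under the `free` policy) with box bounds three decades beyond the
reciprocal free-ligand range and w ∈ [0.05, 50]. Site counts are fixed at
n_j = 1 by default, matching the printed form of the affinity-index
model; the `free` policy is exploratory. Multi-start is deterministic and
hierarchical: the single-class scan crosses a decade-spaced k grid
bracketing 1/[L]_free with w starts {0.5, 1, 2, 4, 8}; each additional
class is seeded from the best previous solution crossed with a fresh
k grid and w starts {1, 3, 8}. This visits ~200 solver runs instead of
the ~10⁴ of a full Cartesian grid and reaches the same optima on the
forward model. Class count is selected by AICc
(N·ln(RSS/N) + 2p + 2p(p+1)/(N−p−1)) with the RSS floored at
(10⁻⁹·max|Σν|)²·N to keep the criterion finite on exact fits; ties break
toward fewer classes. Class counts whose parameter count exceeds half the
data are not attempted. Standard errors come from the Gauss–Newton
covariance at the optimum, delta-transformed out of log space.

## Time-resolved fitting

Tail fitting from the peak channel onward; no instrument-response
deconvolution (at 2–7 ns lifetimes with a compact TCSPC unit, tail
fitting is standard and the IRF mostly affects the rising edge that is
excluded). Residuals are weighted 1/√max(counts, 1) (Poisson variance).
Initialisation is deterministic: the long component from a log-linear fit
to the later half of the positive-count channels, the short component
from the early residual above the long tail. Amplitudes are normalised to
Σα = 1 on output and components ordered by descending lifetime. The
average lifetime Σα_iτ_i²/Σα_iτ_i is defined for one or two components
only; requesting more components is an error rather than a silent
extension of the formula.

## Synthetic data generator

The generator emulates: a tryptophan emission band as a log-normal
(Siano–Metzler) shape peaking at 340 nm, FWHM 60 nm, asymmetry 0.25; a
ligand absorption band as a two-sided Gaussian peaking at 326 nm with
σ_blue = 20 nm and σ_red = 28 nm, scaled by ε = 18 700 M⁻¹cm⁻¹ — widths
chosen once so the blue half of the emission window (305–340 nm) absorbs
more than the red half (360–400 nm) and the uncorrected apparent peak
shifts ≥ 3 nm to the red at 32 µM ligand (measured: 11 nm). Occupancy
follows the two-class affinity-index model with defaults
k = (2.3×10⁵, 1.3×10⁵) M⁻¹, w = (2.93, 8.15), n_j = 1; free ligand is
solved from mass conservation by bracketed root finding (Brent) to
~10⁻¹⁵ relative, so the conservation identity is exact at every design
point.

Static quenching is modelled as a wavelength-independent multiplicative
factor 1 − q·Σν/Σn_j with quench efficiency q = 0.45, chosen so F₀/F
reaches ≈ 1.8 at the top of the 4 µM-protein ladder — the quench depth of
a moderate-affinity albumin binder. Two consequences are deliberate and
tested: quench percentage is exactly proportional to binding density
(which makes the IDF level-matching exact up to ladder interpolation),
and intensity- and area-mode analyses agree exactly. The
occupancy-to-quench mapping is a simulator convention: real systems need
no such forward model, and nothing in the analysis modules assumes it.

Default design: ligand 0–32 µM in 2 µM steps; protein 2/4/8 µM at 288 K
for the IDF; a single protein concentration at 288/298/308 K serves the
Stern–Volmer/Van't Hoff chain. Noise is additive Gaussian with standard
deviation given relative to the zero-ligand peak; the default is 0 (clean
forward model — noise levels are an explicit experimental condition, not
something to bake in silently). Decays are Poisson counts around the
exponential model on a 0–50 ns grid at 10⁴ peak counts; by default the
lifetime is ligand-independent (pure static quenching), with an option to
let it fall linearly to 6.28 ns at the top of the ladder (mild
collisional admixture). CD curves are a deterministic double negative
Gaussian with minima at 208 and 222 nm (σ = 4 nm keeps the two minima on
their band centres despite overlap).

What the generator does **not** emulate: Raman/Rayleigh scatter,
instrument spectral response, wavelength-dependent quenching, ligand
fluorescence bleed-through above 400 nm, detector nonlinearity, or IRF
convolution in the decays. Tests passing on generator data therefore
validate the estimators under the stated model, not robustness to those
instrumental artefacts.

## Problem sizes

Analyses run on the study-sized design throughout: 17-point ladders,
three protein concentrations, 20 quench levels, 30-point forward curves,
1000-channel decays; the noisy-recovery check uses 100 generator seeds at
1% noise and reports medians.

## Known limitations

* The IDF inversion inherits the titration step size: on a 2 µM ladder
  the steep second transition (w ≈ 8) produces binding-density errors up
  to ~0.1 sites at individual levels and a low bias of a few percent in
  the recovered affinity indexes. Finer ladders reduce it.
* The double-log model assumes one effective site class; on cooperative
  data its Ka and n are apparent values, which is exactly why the IDF
  route exists.
* Van't Hoff assumes temperature-independent ΔH; no heat-capacity term
  is offered.
* Hill-parameter uncertainties are asymptotic (no bootstrap bands).
* The affinity index w_j is treated as a fitted exponent; with n_j = 1 a
  w_j exceeding 1 is reported as printed, with no mechanistic
  reinterpretation.
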