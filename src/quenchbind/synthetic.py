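"""Ground-truthed synthetic data: titration spectra with cooperative static
quenching and inner-filter attenuation, TCSPC decays, and CD curves.

The simulator is the package's reference forward model.  Its occupancy model
is the two-class Hill ("affinity index") expression

    sum_nu(L_free) = sum_j n_j (k_j L_free)^{w_j} / (1 + (k_j L_free)^{w_j})

with defaults n_j = 1, k = (2.3e5, 1.3e5) M^-1, w = (2.93, 8.15): two
cooperative sites on serum albumin with moderate binding constants.  Free
ligand is obtained at every design point by solving the mass-conservation
identity

    L_total = L_free + sum_nu(L_free) * P_total

exactly (bracketed root finding), so the conservation law holds to numerical
round-off at every simulated point.

Observation model.  Static quenching multiplies the whole true emission band
by ``1 - quench_efficiency * sum_nu / sum(n_j)`` — a wavelength-independent
factor, i.e. a single fluorophore class equally accessible to the quencher.
The observed spectrum then attenuates the true one by the inner filter:

    F_obs(lam) = F_true(lam) * 10**(-(A_ex + A(lam)) / 2)

with A from ligand Beer-Lambert at the *total* ligand concentration.  The
occupancy-to-quench mapping is a simulator convention (a forward model is
needed to generate data; nothing downstream assumes it), but it is chosen so
the quench percentage is exactly proportional to the binding density, which
is what makes the interaction-density-function analysis exact on noiseless
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import bands
from .spectra import EPSILON_LIGAND, Spectrum, ligand_absorbance


@dataclass(frozen=True)
class SiteClass:
    """One class of binding sites: n sites, binding constant k (M^-1),
    affinity index (Hill exponent) w."""
    n: float
    k: float
    w: float


DEFAULT_SITE_CLASSES = (SiteClass(1.0, 2.3e5, 2.93),
                        SiteClass(1.0, 1.3e5, 8.15))


@dataclass
class GroundTruth:
    """Hidden parameters of the simulator, against which recovery is scored.

    Defaults mirror the study design: titration 0-32 uM ligand in 2 uM
    steps at protein 2/4/8 uM and 288 K (the IDF design); excitation
    295 nm, emission grid 305-500 nm; tau0 = 6.71 ns, dropping to 6.28 ns
    at the top of the ladder when ``tau_top_ns`` is set (mild collisional
    contribution).  ``noise_sigma`` is the additive Gaussian noise standard
    deviation relative to the zero-ligand peak intensity; the default is a
    clean (noise-free) forward model.
    """
    site_classes: tuple = DEFAULT_SITE_CLASSES
    quench_efficiency: float = 0.45
    emission_peak_nm: float = bands.EMISSION_PEAK_NM
    emission_fwhm_nm: float = bands.EMISSION_FWHM_NM
    emission_asym: float = bands.EMISSION_ASYMMETRY
    abs_peak_nm: float = bands.ABS_PEAK_NM
    abs_sigma_blue: float = bands.ABS_SIGMA_BLUE_NM
    abs_sigma_red: float = bands.ABS_SIGMA_RED_NM
    epsilon: float = EPSILON_LIGAND
    tau0_ns: float = 6.71
    tau_top_ns: float | None = None
    protein_concs: tuple = (2e-6, 4e-6, 8e-6)
    ligand_max: float = 32e-6
    ligand_step: float = 2e-6
    temperature_K: float = 288.0
    excitation_nm: float = 295.0
    emission_grid: tuple = (305.0, 500.0, 1.0)
    absorbance_grid: tuple = (240.0, 500.0, 1.0)
    peak_intensity: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0

    @property
    def ligand_ladder(self) -> np.ndarray:
        n = int(round(self.ligand_max / self.ligand_step))
        return np.arange(n + 1) * self.ligand_step

    @property
    def total_sites(self) -> float:
        return sum(sc.n for sc in self.site_classes)

    def occupancy(self, free_ligand) -> np.ndarray:
        """Binding density sum_nu at free ligand concentration(s) in M."""
        lf = np.asarray(free_ligand, float)
        nu = np.zeros_like(lf)
        pos = lf > 0
        for sc in self.site_classes:
            x = (sc.k * lf[pos]) ** sc.w
            nu[pos] += sc.n * x / (1.0 + x)
        return nu if nu.ndim else float(nu)

    def emission_shape(self, lam):
        return bands.lognormal_band(lam, self.emission_peak_nm,
                                    self.emission_fwhm_nm, self.emission_asym)

    def absorbance_shape(self, lam):
        return bands.asymmetric_gaussian(lam, self.abs_peak_nm,
                                         self.abs_sigma_blue,
                                         self.abs_sigma_red)

    def absorbance_spectrum(self, ligand_M: float) -> Spectrum:
        lo, hi, step = self.absorbance_grid
        lam = np.arange(lo, hi + step / 2, step)
        return ligand_absorbance(ligand_M, lam,
                                 band_shape=self.absorbance_shape,
                                 epsilon=self.epsilon)


@dataclass
class TitrationSeries:
    """A ligand-concentration ladder at fixed protein concentration and
    temperature, with one observed spectrum per step.

    ``true_spectra`` (inner-filter-free, noise-free) and per-step ligand
    ``absorbance_spectra`` are carried alongside when produced by the
    simulator; real data would provide measured absorbances instead.
    """
    protein_conc: float
    temperature_K: float
    ligand_concs: np.ndarray
    spectra: list
    true_spectra: list = field(default_factory=list)
    absorbance_spectra: list = field(default_factory=list)

    def __post_init__(self):
        self.ligand_concs = np.asarray(self.ligand_concs, float)
        if len(self.spectra) != len(self.ligand_concs):
            raise ValueError("one spectrum per ligand concentration required")
        if not np.all(np.diff(self.ligand_concs) > 0):
            raise ValueError("ligand ladder must be strictly increasing")

    def corrected(self) -> "TitrationSeries":
        """Inner-filter-correct every spectrum using the per-step ligand
        absorbance (simulated Beer-Lambert or measured)."""
        from .spectra import inner_filter_correct
        if not self.absorbance_spectra:
            raise ValueError("no absorbance spectra attached")
        corr = [inner_filter_correct(s, a)
                for s, a in zip(self.spectra, self.absorbance_spectra)]
        return TitrationSeries(self.protein_conc, self.temperature_K,
                               self.ligand_concs, corr,
                               self.true_spectra, self.absorbance_spectra)


# ---------------------------------------------------------------------------

def solve_free_ligand(total_ligand: float, protein: float,
                      truth: GroundTruth) -> tuple[float, float]:
    """Free ligand concentration and binding density at one design point.

    Solves ``L_total - L_free - sum_nu(L_free) * P = 0`` for the unique root
    on [0, L_total]; the conservation identity holds to better than 1e-12
    relative.  Returns ``(L_free, sum_nu)``.
    """
    if total_ligand < 0 or protein < 0:
        raise ValueError("concentrations must be non-negative")
    if total_ligand == 0:
        return 0.0, 0.0
    if protein == 0:
        return float(total_ligand), float(truth.occupancy(total_ligand))

    def balance(lf):
        return total_ligand - lf - truth.occupancy(lf) * protein

    # balance(0) = L_total > 0 and balance(L_total) <= 0: always bracketed
    lf = brentq(balance, 0.0, total_ligand, xtol=1e-18, rtol=1e-15,
                maxiter=200)
    return float(lf), float(truth.occupancy(lf))


def simulate_titration(truth: GroundTruth) -> list[TitrationSeries]:
    """Simulate the full titration design: one series per protein
    concentration, each with observed, hidden-true and absorbance spectra."""
    lo, hi, step = truth.emission_grid
    lam = np.arange(lo, hi + step / 2, step)
    shape = truth.emission_shape(lam)
    rng = np.random.default_rng(truth.seed)
    out = []
    for prot in truth.protein_concs:
        obs_list, true_list, abs_list = [], [], []
        for ltot in truth.ligand_ladder:
            _, nu = solve_free_ligand(ltot, prot, truth)
            quench = 1.0 - truth.quench_efficiency * nu / truth.total_sites
            if quench <= 0:
                raise ValueError("design yields non-positive intensity")
            f_true = truth.peak_intensity * shape * quench
            absorb = truth.absorbance_spectrum(ltot)
            a_ex = absorb.value_at(truth.excitation_nm)
            a_em = np.interp(lam, absorb.wavelengths, absorb.values)
            f_obs = f_true * 10.0 ** (-(a_ex + a_em) / 2.0)
            if truth.noise_sigma > 0:
                f_obs = f_obs + rng.normal(
                    0.0, truth.noise_sigma * truth.peak_intensity, lam.size)
                f_obs = np.maximum(f_obs, 0.0)
            meta = {"excitation_nm": truth.excitation_nm,
                    "temperature_K": truth.temperature_K,
                    "protein_M": prot, "ligand_M": ltot}
            obs_list.append(Spectrum("emission", lam, f_obs, dict(meta)))
            true_list.append(Spectrum("emission", lam, f_true,
                                      dict(meta, corrected=True)))
            abs_list.append(absorb)
        out.append(TitrationSeries(prot, truth.temperature_K,
                                   truth.ligand_ladder, obs_list,
                                   true_list, abs_list))
    return out


def simulate_decay(truth: GroundTruth, ligand: float = 0.0,
                   peak_counts: float = 1e4, t_max_ns: float = 50.0,
                   dt_ns: float = 0.05, noise: bool = True,
                   components=None, rng=None):
    """Simulate a TCSPC decay trace at one ligand concentration.

    Pure static quenching leaves the lifetime at ``tau0_ns``; when
    ``tau_top_ns`` is set the lifetime falls linearly with ligand to that
    value at the top of the ladder (mild collisional contribution).
    ``components`` overrides with explicit ``[(alpha, tau_ns), ...]``.
    Counts are Poisson-distributed around the model when ``noise``.
    """
    from .timeresolved import DecayTrace
    if peak_counts < 100:
        raise ValueError("peak counts must be >= 100")
    t = np.arange(0.0, t_max_ns + dt_ns / 2, dt_ns)
    if components is None:
        tau = truth.tau0_ns
        if truth.tau_top_ns is not None and truth.ligand_max > 0:
            frac = min(ligand / truth.ligand_max, 1.0)
            tau = truth.tau0_ns + frac * (truth.tau_top_ns - truth.tau0_ns)
        components = [(1.0, tau)]
    model = np.zeros_like(t)
    alpha_sum = sum(a for a, _ in components)
    for a, tau_i in components:
        model += (a / alpha_sum) * np.exp(-t / tau_i)
    model *= peak_counts
    if noise:
        if rng is None:
            rng = np.random.default_rng(truth.seed)
        counts = rng.poisson(model).astype(float)
    else:
        counts = model
    return DecayTrace(t, counts, meta={"excitation_nm": 295.0,
                                       "emission_nm": 340.0,
                                       "ligand_M": ligand})


def simulate_cd(amplitudes=(-12.0, -11.0), centers=(208.0, 222.0),
                sigmas=(4.0, 4.0), grid=(200.0, 260.0, 0.5),
                noise_sigma: float = 0.0, seed: int = 0) -> Spectrum:
    """Deterministic double-Gaussian CD band model with negative minima at
    208 and 222 nm (alpha-helical signature), plus optional noise."""
    lo, hi, step = grid
    lam = np.arange(lo, hi + step / 2, step)
    theta = np.zeros_like(lam)
    for amp, cen, sig in zip(amplitudes, centers, sigmas):
        theta += amp * np.exp(-((lam - cen) ** 2) / (2.0 * sig ** 2))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sigma, lam.size)
    return Spectrum("cd", lam, theta, {"temperature_K": 298.0})


# ---------------------------------------------------------------------------

def simulate_binding_curve_1to1(Ka: float, protein: float, ligand_concs,
                                F0: float = 1000.0) -> np.ndarray:
    """Fluorescence signals for a 1:1 binding model (single site, no
    cooperativity): F = F0 * (1 - theta) with theta the protein occupancy.

    Solves the exact quadratic for free ligand; used as the noiseless
    forward model behind the double-log binding-constant analysis.
    """
    lig = np.asarray(ligand_concs, float)
    out = np.empty_like(lig)
    for i, ltot in enumerate(lig):
        if ltot == 0:
            out[i] = F0
            continue
        # Ka*Lf^2 + (1 + Ka*P - Ka*Ltot)*Lf - Ltot = 0
        b = 1.0 + Ka * protein - Ka * ltot
        lf = (-b + np.sqrt(b * b + 4.0 * Ka * ltot)) / (2.0 * Ka)
        theta = Ka * lf / (1.0 + Ka * lf)
        out[i] = F0 * (1.0 - theta)
    return out
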