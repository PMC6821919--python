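"""Quenching-curve construction, Stern-Volmer analysis, mechanism
classification and the double-log binding-constant fit.

The Stern-Volmer law for a single accessible fluorophore class,

    F0 / F = 1 + K_SV [L] = 1 + k_q tau0 [L],

is fitted with the intercept fixed at 1 by default (the law has no free
intercept).  The bimolecular quenching rate constant k_q = K_SV / tau0
diagnoses the mechanism: collisional (diffusive) quenching cannot exceed
~1e10 M^-1 s^-1, so a k_q orders of magnitude above that indicates static
(ground-state complex) quenching, confirmed when the lifetime ratio
tau0/tau stays near unity while F0/F grows.

The binding constant and apparent site number come from the double-log
regression

    log((F0-F)/F) = n log Ka - n log( 1 / ([L] - ((F0-F)/F0) [P]) )

run in a single pass exactly as written (the bound-ligand correction uses
(F0-F)/F0 with no iteration).

Curves can be built in *intensity* mode (signal read at one wavelength,
340 nm by default) or *area* mode (trapezoidal band area, 305-400 nm by
default).  Both require inner-filter-corrected spectra — correcting the
whole spectrum first is a sine qua non for either read-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import integrate_band

COLLISIONAL_KQ_LIMIT = 1e10  # M^-1 s^-1, upper bound for diffusive quenching

DEFAULT_READ_NM = 340.0
DEFAULT_AREA_WINDOW = (305.0, 400.0)


class QuenchingError(ValueError):
    pass


@dataclass
class QuenchingCurve:
    """Per-ligand-concentration fluorescence ratios F0/F (or A0/A).

    ``ligand_conc`` is the ascending ladder in M with the zero-ligand
    reference first; ``ratio[0] == 1`` by construction.
    """
    ligand_conc: np.ndarray
    ratio: np.ndarray
    mode: str
    read: object  # wavelength (intensity mode) or (lo, hi) window (area)
    temperature_K: float | None = None
    protein_conc: float | None = None

    def __post_init__(self):
        self.ligand_conc = np.asarray(self.ligand_conc, float)
        self.ratio = np.asarray(self.ratio, float)
        if self.mode not in ("intensity", "area"):
            raise QuenchingError(f"unknown mode {self.mode!r}")
        if self.ligand_conc.shape != self.ratio.shape:
            raise QuenchingError("ligand_conc and ratio length mismatch")
        if not np.all(np.diff(self.ligand_conc) > 0):
            raise QuenchingError("ligand concentrations must be increasing")
        if self.ligand_conc[0] != 0:
            raise QuenchingError("curve must start at the zero-ligand point")
        if abs(self.ratio[0] - 1.0) > 1e-12:
            raise QuenchingError("reference ratio must equal 1")
        if np.any(self.ratio <= 0):
            raise QuenchingError("ratios must be positive")


def build_curve(series, mode: str = "intensity", read=None) -> QuenchingCurve:
    """Build a :class:`QuenchingCurve` from a titration of corrected spectra.

    ``read`` is the read-out wavelength in nm (intensity mode, default 340)
    or the (lo, hi) integration window (area mode, default 305-400 nm).
    All spectra must carry the inner-filter ``corrected`` flag and the
    series must include the zero-ligand reference.
    """
    if read is None:
        read = DEFAULT_READ_NM if mode == "intensity" else DEFAULT_AREA_WINDOW
    if series.ligand_concs[0] != 0:
        raise QuenchingError("series lacks the zero-ligand reference point")
    for s in series.spectra:
        if not s.is_corrected:
            raise QuenchingError(
                "spectra must be inner-filter corrected before building "
                "quenching curves"
            )
    if mode == "intensity":
        signals = np.array([s.value_at(float(read)) for s in series.spectra])
    elif mode == "area":
        lo, hi = read
        signals = np.array([integrate_band(s, lo, hi)
                            for s in series.spectra])
    else:
        raise QuenchingError(f"unknown mode {mode!r}")
    if np.any(signals <= 0):
        raise QuenchingError("non-positive signal in titration series")
    ratios = signals[0] / signals
    ratios[0] = 1.0
    return QuenchingCurve(series.ligand_concs, ratios, mode, read,
                          temperature_K=series.temperature_K,
                          protein_conc=series.protein_conc)


# ---------------------------------------------------------------------------
# Stern-Volmer
# ---------------------------------------------------------------------------

@dataclass
class SternVolmerResults:
    """Fitted Stern-Volmer parameters."""
    K_SV: float          # M^-1
    K_SV_se: float
    intercept: float     # 1.0 when fixed
    r_squared: float
    k_q: float | None    # M^-1 s^-1, = K_SV / tau0 when tau0 supplied
    tau0: float | None   # s
    mode: str
    temperature_K: float | None
    n_points: int

    def summary(self) -> str:
        lines = [
            "Stern-Volmer fit",
            "-" * 44,
            f"mode:            {self.mode}",
            f"temperature:     {self.temperature_K} K",
            f"n points:        {self.n_points}",
            f"K_SV:            {self.K_SV:.4g} +/- {self.K_SV_se:.2g} M^-1",
            f"intercept:       {self.intercept:.4g}",
            f"r^2:             {self.r_squared:.5f}",
        ]
        if self.k_q is not None:
            lines.append(f"k_q:             {self.k_q:.4g} M^-1 s^-1 "
                         f"(tau0 = {self.tau0:.3g} s)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"K_SV": self.K_SV, "K_SV_se": self.K_SV_se,
                "K_SV_units": "M^-1", "intercept": self.intercept,
                "r_squared": self.r_squared, "k_q": self.k_q,
                "k_q_units": "M^-1 s^-1", "tau0_s": self.tau0,
                "mode": self.mode, "temperature_K": self.temperature_K,
                "n_points": self.n_points}


class SternVolmer:
    """Stern-Volmer model F0/F = 1 + K_SV [L] for a quenching curve.

    Parameters
    ----------
    curve : QuenchingCurve
    tau0 : float, optional
        Unquenched lifetime in seconds; enables k_q = K_SV / tau0.
    fix_intercept : bool, default True
        Fit (ratio - 1) on [L] through the origin (the law's form).  With
        ``False`` an ordinary regression of ratio on [L] is used for
        diagnostics.
    """

    def __init__(self, curve: QuenchingCurve, tau0: float | None = None,
                 fix_intercept: bool = True):
        if curve.ligand_conc.size < 3:
            raise QuenchingError("Stern-Volmer fit requires >= 3 points")
        if tau0 is not None and tau0 <= 0:
            raise QuenchingError("tau0 must be positive")
        self.curve = curve
        self.tau0 = tau0
        self.fix_intercept = fix_intercept

    def fit(self) -> SternVolmerResults:
        x = self.curve.ligand_conc
        y = self.curve.ratio
        n = x.size
        if self.fix_intercept:
            yy = y - 1.0
            sxx = float(np.dot(x, x))
            slope = float(np.dot(x, yy)) / sxx
            resid = yy - slope * x
            dof = n - 1
            s2 = float(np.dot(resid, resid)) / dof if dof > 0 else np.nan
            slope_se = np.sqrt(s2 / sxx)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
            intercept = 1.0
        else:
            res = stats.linregress(x, y)
            slope, intercept = res.slope, res.intercept
            slope_se, r2 = res.stderr, res.rvalue ** 2
        if slope < 0:
            warnings.warn(
                "negative Stern-Volmer slope: fluorescence enhancement, "
                "not quenching", stacklevel=2)
        k_q = slope / self.tau0 if self.tau0 is not None else None
        return SternVolmerResults(
            K_SV=float(slope), K_SV_se=float(slope_se),
            intercept=float(intercept), r_squared=float(r2), k_q=k_q,
            tau0=self.tau0, mode=self.curve.mode,
            temperature_K=self.curve.temperature_K, n_points=n)


def stern_volmer_fit(curve: QuenchingCurve, tau0: float | None = None,
                     fix_intercept: bool = True) -> SternVolmerResults:
    """Functional wrapper around :class:`SternVolmer`."""
    return SternVolmer(curve, tau0=tau0, fix_intercept=fix_intercept).fit()


# ---------------------------------------------------------------------------
# mechanism classification
# ---------------------------------------------------------------------------

@dataclass
class MechanismCall:
    """Quenching-mechanism verdict with the evidence that produced it."""
    verdict: str                 # 'static' | 'dynamic' | 'mixed'
    k_q: float | None
    kq_exceeds_collisional: bool | None
    max_lifetime_deviation: float   # max(tau0/tau - 1)
    max_intensity_deviation: float  # max(F0/F - 1)
    max_ratio_mismatch: float       # max |tau0/tau - F0/F| / (F0/F)

    def summary(self) -> str:
        return (
            f"mechanism: {self.verdict}\n"
            f"  k_q = {self.k_q!r} M^-1 s^-1 "
            f"(collisional limit {COLLISIONAL_KQ_LIMIT:.0e})\n"
            f"  max(tau0/tau - 1)  = {self.max_lifetime_deviation:.4f}\n"
            f"  max(F0/F - 1)      = {self.max_intensity_deviation:.4f}\n"
            f"  max rel |tau0/tau - F0/F| = {self.max_ratio_mismatch:.4f}"
        )


def classify_mechanism(sv: SternVolmerResults, lifetime_ratios,
                       intensity_ratios, equiv_tol: float = 0.05,
                       flat_frac: float = 0.25) -> MechanismCall:
    """Classify the quenching mechanism from the standard diagnostic rules.

    *static*: k_q exceeds the collisional limit (1e10 M^-1 s^-1) and
    tau0/tau stays close to unity — its maximum excursion is below
    ``flat_frac`` of the maximum F0/F excursion — while F0/F grows.

    *dynamic*: tau0/tau tracks F0/F within ``equiv_tol`` relative at every
    point (lifetime and intensity fall together).

    *mixed* otherwise.  Ratio arrays must be aligned on the same ladder.
    """
    tau_r = np.asarray(lifetime_ratios, float)
    int_r = np.asarray(intensity_ratios, float)
    if tau_r.shape != int_r.shape:
        raise QuenchingError("lifetime and intensity ladders do not match")
    max_tau_dev = float(np.max(tau_r - 1.0))
    max_int_dev = float(np.max(int_r - 1.0))
    mismatch = float(np.max(np.abs(tau_r - int_r) / int_r))
    kq_high = sv.k_q is not None and sv.k_q > COLLISIONAL_KQ_LIMIT
    if (kq_high and max_int_dev > 0
            and max_tau_dev < flat_frac * max_int_dev):
        verdict = "static"
    elif mismatch < equiv_tol:
        verdict = "dynamic"
    else:
        verdict = "mixed"
    return MechanismCall(verdict=verdict, k_q=sv.k_q,
                         kq_exceeds_collisional=kq_high,
                         max_lifetime_deviation=max_tau_dev,
                         max_intensity_deviation=max_int_dev,
                         max_ratio_mismatch=mismatch)


# ---------------------------------------------------------------------------
# double-log binding fit
# ---------------------------------------------------------------------------

@dataclass
class BindingResults:
    """Binding constant Ka and apparent site number n from the double-log
    regression."""
    K_a: float        # M^-1
    K_a_se: float
    n_sites: float
    n_sites_se: float
    r_squared: float
    mode: str
    temperature_K: float | None
    n_points: int
    n_dropped: int

    def summary(self) -> str:
        return (
            "Double-log binding fit\n"
            + "-" * 44 + "\n"
            f"mode:         {self.mode}\n"
            f"temperature:  {self.temperature_K} K\n"
            f"K_a:          {self.K_a:.4g} +/- {self.K_a_se:.2g} M^-1\n"
            f"n (sites):    {self.n_sites:.3f} +/- {self.n_sites_se:.3f}\n"
            f"r^2:          {self.r_squared:.5f}\n"
            f"points used:  {self.n_points} (dropped {self.n_dropped})"
        )

    def to_dict(self) -> dict:
        return {"K_a": self.K_a, "K_a_se": self.K_a_se,
                "K_a_units": "M^-1", "n_sites": self.n_sites,
                "n_sites_se": self.n_sites_se, "r_squared": self.r_squared,
                "mode": self.mode, "temperature_K": self.temperature_K,
                "n_points": self.n_points}


class DoubleLogBinding:
    """Double-log binding model for a quenching curve at known protein
    concentration.

    The regression is run in one pass exactly as the model is written:
    y = log10((F0-F)/F) against x = log10([L] - ((F0-F)/F0) [P]), slope n,
    Ka = 10**(intercept / n).  Points whose log arguments are non-positive
    are dropped with a warning; at least 4 usable points are required.
    """

    def __init__(self, curve: QuenchingCurve, protein_conc: float | None = None):
        if protein_conc is None:
            protein_conc = curve.protein_conc
        if protein_conc is None or protein_conc <= 0:
            raise QuenchingError("positive protein concentration required")
        self.curve = curve
        self.protein_conc = float(protein_conc)

    def fit(self) -> BindingResults:
        c = self.curve
        lig = c.ligand_conc[1:]
        ratio = c.ratio[1:]
        if np.all(ratio <= 1):
            raise QuenchingError("no quenching: all ratios <= 1")
        # (F0-F)/F = ratio - 1 ; (F0-F)/F0 = 1 - 1/ratio
        y_arg = ratio - 1.0
        x_arg = lig - (1.0 - 1.0 / ratio) * self.protein_conc
        usable = (y_arg > 0) & (x_arg > 0)
        n_dropped = int(np.sum(~usable))
        if n_dropped:
            warnings.warn(
                f"double-log fit: dropped {n_dropped} point(s) with "
                "non-positive log argument", stacklevel=2)
        if np.sum(usable) < 4:
            raise QuenchingError(
                "double-log fit requires >= 4 points with measurable "
                "quenching")
        x = np.log10(x_arg[usable])
        y = np.log10(y_arg[usable])
        res = stats.linregress(x, y)
        n = res.slope
        if n <= 0:
            raise QuenchingError("non-positive fitted site number")
        Ka = 10.0 ** (res.intercept / n)
        # delta method: Ka = 10^(b/n); var from slope/intercept SEs and
        # their correlation (from the regression design)
        ln10 = np.log(10.0)
        xm = x.mean()
        # cov(slope, intercept) = -xbar * var(slope)
        var_s = res.stderr ** 2
        var_b = res.intercept_stderr ** 2
        cov_sb = -xm * var_s
        dK_db = Ka * ln10 / n
        dK_dn = -Ka * ln10 * res.intercept / n ** 2
        var_K = (dK_db ** 2 * var_b + dK_dn ** 2 * var_s
                 + 2 * dK_db * dK_dn * cov_sb)
        Ka_se = float(np.sqrt(max(var_K, 0.0)))
        return BindingResults(
            K_a=float(Ka), K_a_se=Ka_se, n_sites=float(n),
            n_sites_se=float(res.stderr), r_squared=float(res.rvalue ** 2),
            mode=c.mode, temperature_K=c.temperature_K,
            n_points=int(np.sum(usable)), n_dropped=n_dropped)


def double_log_fit(curve: QuenchingCurve,
                   protein_conc: float | None = None) -> BindingResults:
    """Functional wrapper around :class:`DoubleLogBinding`."""
    return DoubleLogBinding(curve, protein_conc).fit()
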