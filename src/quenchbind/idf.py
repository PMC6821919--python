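"""Interaction Density Function (IDF) analysis: model-free binding-density
extraction, Scatchard diagnostics, and multi-class Hill fitting.

The IDF idea: if two solutions at different total macromolecule
concentrations P show the *same* quench percentage

    dF = |F_obs - F_free| / F_free * 100,

they have the same free-ligand concentration and the same average binding
density sum_nu.  Cutting the family of quench curves (dF versus log total
ligand, one curve per protein concentration) at a horizontal level and
reading off the total ligand concentration of each curve gives points that
obey mass conservation

    L_total = L_free + sum_nu * P_total,

a straight line in P_total whose slope is the binding density and whose
intercept is the free-ligand concentration — no binding model assumed.

The resulting (L_free, sum_nu) pairs are then examined two ways:

* a Scatchard plot (sum_nu / L_free versus sum_nu): a straight declining
  trend for independent identical sites, a convex hump for positive
  cooperativity;
* a multi-class Hill ("affinity index") fit

      sum_nu = sum_j n_j (k_j L)^{w_j} / (1 + (k_j L)^{w_j}),

  with the class count chosen by a corrected Akaike criterion.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .quenching import DEFAULT_AREA_WINDOW, DEFAULT_READ_NM
from .spectra import integrate_band

logger = logging.getLogger(__name__)


class IDFError(ValueError):
    pass


def quench_percentage(F_obs: float, F_free: float) -> float:
    """Percentage quench dF = |F_obs - F_free| / F_free * 100."""
    if F_free <= 0:
        raise IDFError("free-protein signal must be positive")
    return abs(F_obs - F_free) / F_free * 100.0


# ---------------------------------------------------------------------------
# level matching
# ---------------------------------------------------------------------------

@dataclass
class IDFLevel:
    """One horizontal cut through the quench-curve family."""
    delta_F: float                      # % quench
    total_ligand_by_protein: dict       # {P_total M: L_total M}
    sum_nu: float                       # regression slope
    sum_nu_se: float
    free_ligand: float                  # regression intercept, M
    free_ligand_se: float
    r_squared: float
    accepted: bool = True
    reject_reason: str | None = None


@dataclass
class BindingDensityCurve:
    """Ordered (free_ligand, sum_nu) pairs from accepted IDF levels."""
    free_ligand: np.ndarray   # M, ascending
    sum_nu: np.ndarray
    levels: list = field(default_factory=list)

    def __post_init__(self):
        self.free_ligand = np.asarray(self.free_ligand, float)
        self.sum_nu = np.asarray(self.sum_nu, float)
        order = np.argsort(self.free_ligand)
        self.free_ligand = self.free_ligand[order]
        self.sum_nu = self.sum_nu[order]
        if np.any(np.diff(self.sum_nu) < -1e-9 * max(1.0, self.sum_nu.max())):
            warnings.warn(
                "binding density not non-decreasing in free ligand",
                stacklevel=2)


def _series_signals(series, mode, read):
    if read is None:
        read = DEFAULT_AREA_WINDOW if mode == "area" else DEFAULT_READ_NM
    for s in series.spectra:
        if not s.is_corrected:
            raise IDFError("IDF requires inner-filter-corrected spectra")
    if mode == "area":
        lo, hi = read
        return np.array([integrate_band(s, lo, hi) for s in series.spectra])
    return np.array([s.value_at(float(read)) for s in series.spectra])


def match_levels(series_set, levels=20, mode: str = "area", read=None,
                 monotone_tol: float = 2.0, margin_frac: float = 0.02,
                 r2_threshold: float = 0.95) -> list[IDFLevel]:
    """Constant-quench level matching across protein concentrations.

    Parameters
    ----------
    series_set : list of TitrationSeries
        At least two titrations at distinct protein concentrations, same
        temperature, spectra inner-filter corrected.
    levels : int or array
        Number of evenly spaced dF levels inside the common dF range
        (default 20, with a 2% margin at each end), or an explicit grid of
        dF percentages.
    mode, read : signal read-out, as in the quenching module (area over
        305-400 nm by default).
    monotone_tol : float
        Maximum tolerated downward excursion of dF along a ladder, in
        percentage points; noise within the tolerance is flattened by a
        running maximum, larger violations raise an error naming the series.

    For each level, each series' dF(log10 L_total) curve is inverted by
    monotone piecewise-linear interpolation and the resulting
    (P_total, L_total) points regressed: slope = sum_nu, intercept =
    L_free.  Levels with a negative intercept or r^2 below
    ``r2_threshold`` are rejected (kept in the output, flagged).
    """
    if len(series_set) < 2:
        raise IDFError("IDF requires >= 2 protein concentrations")
    prot = [s.protein_conc for s in series_set]
    if len(set(prot)) != len(prot):
        raise IDFError("protein concentrations must be distinct")
    temps = {s.temperature_K for s in series_set}
    if len(temps) > 1:
        raise IDFError("all series must share a temperature")

    curves = []  # (P, dF ascending, log10 L_total)
    for series in series_set:
        if series.ligand_concs[0] != 0:
            raise IDFError("each series needs the zero-ligand reference")
        sig = _series_signals(series, mode, read)
        f0 = sig[0]
        dF = np.array([quench_percentage(v, f0) for v in sig])
        lig = series.ligand_concs
        pos = lig > 0
        dF_pos, lig_pos = dF[pos], lig[pos]
        drops = np.maximum.accumulate(dF_pos) - dF_pos
        if np.max(drops) > monotone_tol:
            raise IDFError(
                f"series at protein {series.protein_conc:g} M: quench "
                f"percentage not monotone (drop {np.max(drops):.2f} > "
                f"tolerance {monotone_tol} percentage points)")
        dF_mono = np.maximum.accumulate(dF_pos)
        # strictly increasing for inversion
        eps = 1e-9
        for i in range(1, dF_mono.size):
            if dF_mono[i] <= dF_mono[i - 1]:
                dF_mono[i] = dF_mono[i - 1] + eps
        curves.append((series.protein_conc, dF_mono, np.log10(lig_pos)))

    lo = max(c[1][0] for c in curves)
    hi = min(c[1][-1] for c in curves)
    if hi <= lo:
        raise IDFError("quench ranges of the series do not overlap")
    if np.isscalar(levels):
        margin = margin_frac * (hi - lo)
        grid = np.linspace(lo + margin, hi - margin, int(levels))
    else:
        grid = np.asarray(levels, float)
        if np.any((grid <= 0) | (grid >= 100)):
            raise IDFError("dF levels must lie in (0, 100)")

    out = []
    P = np.array([c[0] for c in curves])
    for level in grid:
        ltot = np.array([10.0 ** np.interp(level, dF, loglig)
                         for (_, dF, loglig) in curves])
        res = stats.linregress(P, ltot)
        level_obj = IDFLevel(
            delta_F=float(level),
            total_ligand_by_protein=dict(zip(P.tolist(), ltot.tolist())),
            sum_nu=float(res.slope), sum_nu_se=float(res.stderr),
            free_ligand=float(res.intercept),
            free_ligand_se=float(res.intercept_stderr),
            r_squared=float(res.rvalue ** 2))
        if level_obj.free_ligand < 0:
            level_obj.accepted = False
            level_obj.reject_reason = "negative free-ligand intercept"
        elif level_obj.r_squared < r2_threshold:
            level_obj.accepted = False
            level_obj.reject_reason = f"r^2 {level_obj.r_squared:.3f} < {r2_threshold}"
        if not level_obj.accepted:
            logger.info("rejected dF level %.2f%%: %s", level,
                        level_obj.reject_reason)
        out.append(level_obj)
    return out


def binding_density_curve(levels: list[IDFLevel]) -> BindingDensityCurve:
    """Collect accepted levels into a :class:`BindingDensityCurve`."""
    acc = [lv for lv in levels if lv.accepted]
    if not acc:
        raise IDFError("no accepted IDF levels")
    return BindingDensityCurve(
        np.array([lv.free_ligand for lv in acc]),
        np.array([lv.sum_nu for lv in acc]), levels=acc)


# ---------------------------------------------------------------------------
# Scatchard diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ScatchardResult:
    sum_nu: np.ndarray
    nu_over_free: np.ndarray     # sum_nu / L_free
    verdict: str                 # 'positive-cooperative' | 'non-cooperative'
                                 # | 'indeterminate'

    def summary(self) -> str:
        return (f"Scatchard diagnostic over {self.sum_nu.size} points: "
                f"{self.verdict}")


def scatchard(curve: BindingDensityCurve,
              rel_tol: float = 0.02) -> ScatchardResult:
    """Scatchard transform (sum_nu, sum_nu / L_free) with a cooperativity
    verdict.

    *positive-cooperative*: the transformed sequence rises to an interior
    maximum and then falls (the convex hump).  *non-cooperative*: monotone
    decreasing, as for independent identical sites.  Anything else is
    *indeterminate*.  ``rel_tol`` (fraction of the largest transformed
    value, default 2%) absorbs small interpolation or noise wiggles; it is
    asymmetric in the safe direction — a sequence decreasing within
    tolerance is never called cooperative.
    """
    if curve.free_ligand.size < 4:
        raise IDFError("Scatchard diagnostic requires >= 4 points")
    if np.any(curve.free_ligand <= 0):
        raise IDFError("free-ligand concentrations must be positive")
    y = curve.sum_nu / curve.free_ligand
    tol = rel_tol * np.max(np.abs(y))
    diffs = np.diff(y)
    imax = int(np.argmax(y))
    if np.all(diffs <= tol):
        verdict = "non-cooperative"
    elif (0 < imax < y.size - 1
          and np.all(diffs[:imax] >= -tol) and np.all(diffs[imax:] <= tol)):
        verdict = "positive-cooperative"
    else:
        verdict = "indeterminate"
    return ScatchardResult(curve.sum_nu.copy(), y, verdict)


# ---------------------------------------------------------------------------
# multi-class Hill fitting
# ---------------------------------------------------------------------------

@dataclass
class HillClass:
    n: float       # sites in the class
    k: float       # M^-1
    k_se: float
    w: float       # affinity index (Hill exponent)
    w_se: float


@dataclass
class HillResults:
    """Selected multi-class Hill model for a binding-density curve."""
    classes: list                # HillClass, ordered by descending k
    n_classes: int
    rss: float
    aicc: float
    aicc_by_classes: dict        # {j: aicc} over the scan
    n_points: int
    n_policy: str

    def predict(self, free_ligand) -> np.ndarray:
        lf = np.asarray(free_ligand, float)
        out = np.zeros_like(lf)
        for c in self.classes:
            x = (c.k * lf) ** c.w
            out += c.n * x / (1.0 + x)
        return out

    @property
    def total_sites(self) -> float:
        return sum(c.n for c in self.classes)

    def summary(self) -> str:
        lines = [
            "Multi-class Hill fit (affinity-index model)",
            "-" * 56,
            f"classes selected: {self.n_classes}  "
            f"(AICc scan: " + ", ".join(
                f"{j}: {a:.1f}" for j, a in sorted(self.aicc_by_classes.items()))
            + ")",
            f"points: {self.n_points}   RSS: {self.rss:.3e}",
            f"{'class':>5} {'n_j':>5} {'k_j (M^-1)':>14} {'w_j':>8}",
        ]
        for i, c in enumerate(self.classes, 1):
            lines.append(
                f"{i:>5} {c.n:5.2f} {c.k:10.4g} +/- {c.k_se:.2g} "
                f"{c.w:8.3f} +/- {c.w_se:.2g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "classes": [{"n": c.n, "k_M_inv": c.k, "k_se": c.k_se,
                         "w": c.w, "w_se": c.w_se} for c in self.classes],
            "rss": self.rss, "aicc": self.aicc, "n_points": self.n_points,
        }


def _hill_model(lf, ns, ks, ws):
    out = np.zeros_like(lf)
    for n, k, w in zip(ns, ks, ws):
        x = np.exp(w * (np.log(k) + np.log(lf)))
        out += n * x / (1.0 + x)
    return out


class HillBinding:
    """Multi-class Hill model for a binding-density curve.

    Nonlinear least squares in log parameterisation (log k_j, log w_j, and
    log n_j when the site counts are free), with a deterministic
    hierarchical multi-start: the 1-class grid of decade-spaced k values
    crossed with a small set of w starts; each (j+1)-class scan is seeded
    by the best j-class solutions with a fresh grid for the new class.
    The class count is selected over ``1..max_classes`` by the corrected
    Akaike information criterion, ties broken toward fewer classes.

    Parameters
    ----------
    curve : BindingDensityCurve
    max_classes : int, default 3
    n_policy : {'fixed', 'free'}
        'fixed' pins every n_j at 1 (the printed form of the affinity-index
        model); 'free' also fits the per-class site counts.
    """

    _W_STARTS_FULL = (0.5, 1.0, 2.0, 4.0, 8.0)
    _W_STARTS_EXTRA = (1.0, 3.0, 8.0)

    def __init__(self, curve: BindingDensityCurve, max_classes: int = 3,
                 n_policy: str = "fixed"):
        if max_classes < 1:
            raise IDFError("max_classes must be >= 1")
        if n_policy not in ("fixed", "free"):
            raise IDFError("n_policy must be 'fixed' or 'free'")
        lf = curve.free_ligand
        if np.any(lf <= 0):
            raise IDFError("free-ligand concentrations must be positive")
        self.curve = curve
        self.max_classes = max_classes
        self.n_policy = n_policy
        self._ppc = 3 if n_policy == "free" else 2  # params per class

    # -- internals ---------------------------------------------------------

    def _unpack(self, theta, j):
        if self.n_policy == "free":
            ns = np.exp(theta[0::3][:j])
            ks = np.exp(theta[1::3][:j])
            ws = np.exp(theta[2::3][:j])
        else:
            ns = np.ones(j)
            ks = np.exp(theta[0::2][:j])
            ws = np.exp(theta[1::2][:j])
        return ns, ks, ws

    def _pack(self, ns, ks, ws):
        parts = []
        for n, k, w in zip(ns, ks, ws):
            if self.n_policy == "free":
                parts.extend([np.log(n), np.log(k), np.log(w)])
            else:
                parts.extend([np.log(k), np.log(w)])
        return np.array(parts)

    def _solve(self, theta0, j):
        lf, y = self.curve.free_ligand, self.curve.sum_nu
        logk_lo = np.log(1.0 / lf.max()) - 3 * np.log(10)
        logk_hi = np.log(1.0 / lf.min()) + 3 * np.log(10)

        def resid(theta):
            ns, ks, ws = self._unpack(theta, j)
            return _hill_model(lf, ns, ks, ws) - y

        lo, hi = [], []
        for _ in range(j):
            if self.n_policy == "free":
                lo.append(np.log(1e-2)); hi.append(np.log(1e2))
            lo.extend([logk_lo, np.log(0.05)])
            hi.extend([logk_hi, np.log(50.0)])
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi),
                                method="trf", xtol=1e-14, ftol=1e-14,
                                gtol=1e-12, max_nfev=400)
        except Exception:
            return None
        return sol

    def _k_grid(self):
        lf = self.curve.free_ligand
        lo = np.floor(np.log10(1.0 / lf.max())) - 1
        hi = np.ceil(np.log10(1.0 / lf.min())) + 1
        return 10.0 ** np.arange(lo, hi + 0.5, 1.0)

    def _fit_j(self, j, seeds):
        """Best fit with exactly j classes from deterministic starts plus
        ``seeds`` (solutions of the (j-1)-class scan)."""
        starts = []
        kg = self._k_grid()
        if j == 1:
            for k0 in kg:
                for w0 in self._W_STARTS_FULL:
                    starts.append(self._pack([1.0], [k0], [w0]))
        else:
            for seed in seeds:
                ns, ks, ws = seed
                for k0 in kg:
                    for w0 in self._W_STARTS_EXTRA:
                        starts.append(self._pack(
                            list(ns) + [1.0], list(ks) + [k0],
                            list(ws) + [w0]))
        best = None
        for theta0 in starts:
            sol = self._solve(theta0, j)
            if sol is None or not sol.success and sol.status <= 0:
                continue
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
        if best is None:
            raise IDFError(f"Hill fit with {j} classes: no start converged")
        return best

    @staticmethod
    def _aicc(rss, n, p, yscale):
        rss = max(rss, n * (1e-9 * yscale) ** 2)  # floor against log(0)
        aic = n * np.log(rss / n) + 2 * p
        if n - p - 1 > 0:
            aic += 2 * p * (p + 1) / (n - p - 1)
        else:
            aic = np.inf
        return aic

    def _standard_errors(self, sol, j):
        """SEs for k_j and w_j from the Jacobian, delta method from the log
        parameterisation."""
        n, p = self.curve.sum_nu.size, sol.x.size
        rss = 2 * sol.cost
        if n <= p:
            return np.full(p, np.nan)
        J = sol.jac
        try:
            cov = np.linalg.pinv(J.T @ J) * rss / (n - p)
            return np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)

    # -- API ---------------------------------------------------------------

    def fit(self) -> HillResults:
        y = self.curve.sum_nu
        n = y.size
        results, aiccs = {}, {}
        seeds = []
        for j in range(1, self.max_classes + 1):
            p = self._ppc * j
            if n < 2 * p:
                break  # not enough points for this class count
            sol = self._fit_j(j, seeds)
            results[j] = sol
            aiccs[j] = self._aicc(2 * sol.cost, n, p, float(np.max(np.abs(y))))
            ns, ks, ws = self._unpack(sol.x, j)
            seeds = [(ns, ks, ws)]
        if not results:
            raise IDFError("too few points for even a single Hill class")
        best_j = min(aiccs, key=lambda j: (round(aiccs[j], 9), j))
        sol = results[best_j]
        ns, ks, ws = self._unpack(sol.x, best_j)
        log_se = self._standard_errors(sol, best_j)
        classes = []
        for i in range(best_j):
            if self.n_policy == "free":
                k_se = ks[i] * log_se[3 * i + 1]
                w_se = ws[i] * log_se[3 * i + 2]
            else:
                k_se = ks[i] * log_se[2 * i]
                w_se = ws[i] * log_se[2 * i + 1]
            classes.append(HillClass(n=float(ns[i]), k=float(ks[i]),
                                     k_se=float(k_se), w=float(ws[i]),
                                     w_se=float(w_se)))
        classes.sort(key=lambda c: -c.k)
        return HillResults(classes=classes, n_classes=best_j,
                           rss=float(2 * sol.cost), aicc=float(aiccs[best_j]),
                           aicc_by_classes={j: float(a)
                                            for j, a in aiccs.items()},
                           n_points=n, n_policy=self.n_policy)


def hill_fit(curve: BindingDensityCurve, max_classes: int = 3,
             n_policy: str = "fixed") -> HillResults:
    """Functional wrapper around :class:`HillBinding`."""
    return HillBinding(curve, max_classes=max_classes,
                       n_policy=n_policy).fit()
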