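"""Multiexponential fitting of TCSPC fluorescence decays and
amplitude-weighted average lifetimes.

The decay model is I(t) = sum_i alpha_i exp(-t / tau_i) with one or two
components; the intensity-weighted average lifetime is

    tau_avg = sum(alpha_i tau_i^2) / sum(alpha_i tau_i).

Fitting is tail fitting (no instrument-response deconvolution): residuals
start at the peak channel and are weighted by the Poisson standard
deviation sqrt(max(counts, 1)).  Initialisation is deterministic, from
log-linear slopes of the decay tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class DecayError(ValueError):
    pass


@dataclass
class DecayTrace:
    """A TCSPC histogram: time grid (ns, ascending from 0) and counts."""
    time: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.counts = np.asarray(self.counts, float)
        if self.time.shape != self.counts.shape:
            raise DecayError("time and counts length mismatch")
        if not np.all(np.diff(self.time) > 0):
            raise DecayError("time grid must be strictly increasing")
        if np.any(self.counts < 0):
            raise DecayError("counts must be non-negative")


def read_decay(path) -> DecayTrace:
    """Read a two-column (time_ns, counts) file with '#' metadata header."""
    meta = {}
    times, counts = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, _, v = body.partition(":")
                    try:
                        meta[k.strip()] = float(v)
                    except ValueError:
                        meta[k.strip()] = v.strip()
                continue
            if not line.strip():
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) < 2:
                raise DecayError(f"{path}: line {lineno}: expected 2 columns")
            times.append(float(fields[0]))
            counts.append(float(fields[1]))
    return DecayTrace(np.array(times), np.array(counts), meta)


def write_decay(path, trace: DecayTrace) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in trace.meta.items():
            fh.write(f"# {k}: {v}\n")
        for t, c in zip(trace.time, trace.counts):
            fh.write(f"{float(t)!r}\t{float(c)!r}\n")


@dataclass
class DecayFit:
    """Fitted decay components (amplitudes normalised to sum 1, ordered by
    descending lifetime) and goodness of fit."""
    components: list            # [(alpha_i, tau_i ns), ...]
    tau_avg: float              # ns
    chi2_reduced: float
    n_points: int

    def summary(self) -> str:
        lines = ["Decay fit", "-" * 40]
        for i, (a, tau) in enumerate(self.components, 1):
            lines.append(f"component {i}: alpha = {a:.4f}  tau = {tau:.4f} ns")
        lines.append(f"tau_avg = {self.tau_avg:.4f} ns   "
                     f"chi2_red = {self.chi2_reduced:.3f}")
        return "\n".join(lines)


def average_lifetime(fit_or_components) -> float:
    """Intensity-weighted average lifetime sum(a t^2) / sum(a t), in ns.

    Accepts a :class:`DecayFit` or a list of (alpha, tau) pairs (one or two
    components); scale-invariant in the amplitudes.
    """
    comps = getattr(fit_or_components, "components", fit_or_components)
    if not 1 <= len(comps) <= 2:
        raise DecayError("average lifetime defined for 1 or 2 components")
    a = np.array([c[0] for c in comps], float)
    tau = np.array([c[1] for c in comps], float)
    if np.any(tau <= 0):
        raise DecayError("lifetimes must be positive")
    return float(np.sum(a * tau ** 2) / np.sum(a * tau))


def _tail_init(t, c, n_components):
    """Deterministic initial guesses from log-linear tail slopes."""
    pos = c > 0
    t_pos, c_pos = t[pos], c[pos]
    if t_pos.size < 4:
        raise DecayError("too few positive-count channels")
    # long component from the last half of the positive-count range
    half = t_pos.size // 2
    s1, b1 = np.polyfit(t_pos[half:], np.log(c_pos[half:]), 1)
    tau1 = -1.0 / s1 if s1 < 0 else (t_pos[-1] - t_pos[0])
    a1 = np.exp(b1)
    if n_components == 1:
        return [(a1, tau1)]
    # short component from the early residual above the long tail
    resid = c_pos - a1 * np.exp(-t_pos / tau1)
    early = resid[: max(half, 4)]
    te = t_pos[: max(half, 4)]
    good = early > 0
    if np.sum(good) >= 2:
        s2, b2 = np.polyfit(te[good], np.log(early[good]), 1)
        tau2 = -1.0 / s2 if s2 < 0 else tau1 / 3.0
        a2 = np.exp(b2)
    else:
        tau2, a2 = tau1 / 3.0, 0.3 * a1
    tau2 = min(max(tau2, 1e-3), 0.9 * tau1)
    return [(a1, tau1), (max(a2, 1e-3 * a1), tau2)]


class ExponentialDecay:
    """Mono- or bi-exponential decay model for a TCSPC trace.

    Least squares on log-parameterised amplitudes and lifetimes with
    Poisson weights; the fit window starts at the peak channel (tail
    fitting, no deconvolution).  Requires >= 10 points spanning at least
    three lifetimes of the slowest component.
    """

    def __init__(self, trace: DecayTrace, n_components: int = 1):
        if n_components not in (1, 2):
            raise DecayError("n_components must be 1 or 2")
        if np.all(trace.counts == 0):
            raise DecayError("all-zero decay trace")
        self.trace = trace
        self.n_components = n_components

    def fit(self) -> DecayFit:
        t_all, c_all = self.trace.time, self.trace.counts
        start = int(np.argmax(c_all))
        t = t_all[start:] - t_all[start]
        c = c_all[start:]
        if t.size < 10:
            raise DecayError("decay fit requires >= 10 points after the peak")
        init = _tail_init(t, c, self.n_components)
        theta0 = np.concatenate([[np.log(a), np.log(tau)] for a, tau in init])
        sigma = np.sqrt(np.maximum(c, 1.0))

        def resid(theta):
            model = np.zeros_like(t)
            for i in range(self.n_components):
                a = np.exp(theta[2 * i])
                tau = np.exp(theta[2 * i + 1])
                model += a * np.exp(-t / tau)
            return (model - c) / sigma

        sol = least_squares(resid, theta0, method="lm", xtol=1e-14,
                            ftol=1e-14, gtol=1e-14, max_nfev=5000)
        if not sol.success:
            raise DecayError(f"decay fit did not converge: {sol.message}")
        comps = [(np.exp(sol.x[2 * i]), np.exp(sol.x[2 * i + 1]))
                 for i in range(self.n_components)]
        comps.sort(key=lambda c_: -c_[1])
        total_a = sum(a for a, _ in comps)
        comps = [(a / total_a, tau) for a, tau in comps]
        span = t[-1] / max(tau for _, tau in comps)
        if span < 3:
            raise DecayError(
                f"trace spans only {span:.1f} lifetimes; >= 3 required")
        dof = max(t.size - 2 * self.n_components, 1)
        chi2 = float(np.sum(resid(sol.x) ** 2)) / dof
        return DecayFit(components=comps, tau_avg=average_lifetime(comps),
                        chi2_reduced=chi2, n_points=int(t.size))


def fit_decay(trace: DecayTrace, n_components: int = 1) -> DecayFit:
    """Functional wrapper around :class:`ExponentialDecay`."""
    return ExponentialDecay(trace, n_components).fit()


def lifetime_ratio_series(fits_by_ligand: dict) -> dict:
    """tau0/tau per ligand concentration, from fits keyed by ligand (M).

    The zero-ligand reference must be present.  Feeds
    :func:`quenchbind.quenching.classify_mechanism`.
    """
    if not fits_by_ligand:
        raise DecayError("empty fit series")
    if 0 not in fits_by_ligand and 0.0 not in fits_by_ligand:
        raise DecayError("zero-ligand reference fit missing")
    tau0 = average_lifetime(fits_by_ligand[0.0 if 0.0 in fits_by_ligand else 0])
    return {lig: tau0 / average_lifetime(f)
            for lig, f in sorted(fits_by_ligand.items())}
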