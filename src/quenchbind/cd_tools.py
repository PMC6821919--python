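"""Circular dichroism utilities: mean residue ellipticity conversion and
negative-band location.

Raw ellipticity theta (millidegrees) is normalised to mean residue
ellipticity

    [theta] = theta / (10 * [P] * l * n)

with [P] the molar protein concentration (mol/L), l the path length in cm
and n the residue count (584 for rat serum albumin), giving
deg cm^2 dmol^-1.  Negative bands at 208 nm (pi-pi*) and 222 nm (n-pi*)
are the alpha-helical signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

RSA_N_RESIDUES = 584


class CDError(ValueError):
    pass


def mean_residue_ellipticity(theta_mdeg, P: float, l_cm: float,
                             n_res: int = RSA_N_RESIDUES):
    """Convert ellipticity (mdeg) to mean residue ellipticity
    (deg cm^2 dmol^-1).  Linear in theta; accepts scalars or arrays."""
    if P <= 0 or l_cm <= 0 or n_res < 1:
        raise CDError("concentration, path and residue count must be positive")
    return np.asarray(theta_mdeg, float) / (10.0 * P * l_cm * n_res)


def ellipticity_from_mre(mre, P: float, l_cm: float,
                         n_res: int = RSA_N_RESIDUES):
    """Exact inverse of :func:`mean_residue_ellipticity`."""
    if P <= 0 or l_cm <= 0 or n_res < 1:
        raise CDError("concentration, path and residue count must be positive")
    return np.asarray(mre, float) * (10.0 * P * l_cm * n_res)


@dataclass
class CDRecord:
    """One CD observation with the quantities needed for normalisation."""
    theta_mdeg: float
    protein_conc: float   # M
    path_cm: float
    n_residues: int = RSA_N_RESIDUES

    @property
    def mre(self) -> float:
        return float(mean_residue_ellipticity(
            self.theta_mdeg, self.protein_conc, self.path_cm,
            self.n_residues))


def band_minima(cd: Spectrum) -> list[float]:
    """Wavelengths (nm) of local minima with negative ellipticity.

    Interior points strictly below both neighbours and below zero; an empty
    list is a valid result (no negative bands).
    """
    if cd.kind != "cd":
        raise CDError("expected a CD spectrum")
    lam, v = cd.wavelengths, cd.values
    out = []
    for i in range(1, lam.size - 1):
        if v[i] < 0 and v[i] < v[i - 1] and v[i] <= v[i + 1]:
            out.append(float(lam[i]))
    return out
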