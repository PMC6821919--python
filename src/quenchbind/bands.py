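"""Analytic band shapes shared by the simulator and the Beer-Lambert helper.

Both shapes are unit-normalised (value 1 at the band maximum) so they can be
scaled by a peak intensity or by epsilon * c * l.
"""

from __future__ import annotations

import numpy as np

# defaults for the tryptophan emission band and the ligand absorption band
EMISSION_PEAK_NM = 340.0
EMISSION_FWHM_NM = 60.0
EMISSION_ASYMMETRY = 0.25

ABS_PEAK_NM = 326.0
ABS_SIGMA_BLUE_NM = 20.0
ABS_SIGMA_RED_NM = 28.0


def lognormal_band(wavelengths, peak_nm=EMISSION_PEAK_NM,
                   fwhm_nm=EMISSION_FWHM_NM, asym=EMISSION_ASYMMETRY):
    """Log-normal (Siano-Metzler) band shape, unit height at ``peak_nm``.

    ``asym`` > 0 skews the band to the red, the natural asymmetry of protein
    emission bands.  Outside the band's support the value is 0.
    """
    lam = np.asarray(wavelengths, float)
    arg = 1.0 + 2.0 * asym * (lam - peak_nm) / fwhm_nm
    out = np.zeros_like(lam)
    ok = arg > 0
    out[ok] = np.exp(-np.log(2.0) * (np.log(arg[ok]) / asym) ** 2)
    return out


def asymmetric_gaussian(wavelengths, peak_nm=ABS_PEAK_NM,
                        sigma_blue=ABS_SIGMA_BLUE_NM,
                        sigma_red=ABS_SIGMA_RED_NM):
    """Two-sided Gaussian, unit height at ``peak_nm``.

    A wider red flank (``sigma_red`` > ``sigma_blue``) keeps substantial
    absorbance over the blue half of the emission band (305-340 nm) while
    decaying over the red half (360-400 nm) — the asymmetric overlap that
    makes an uncorrected titration look red-shifted.
    """
    lam = np.asarray(wavelengths, float)
    sigma = np.where(lam < peak_nm, sigma_blue, sigma_red)
    return np.exp(-((lam - peak_nm) ** 2) / (2.0 * sigma ** 2))


def ligand_absorbance_shape(wavelengths):
    """Default unit-normalised ligand absorption band (326 nm maximum)."""
    return asymmetric_gaussian(wavelengths)
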