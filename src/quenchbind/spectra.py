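"""Optical spectra: containers, file I/O, baseline subtraction, inner-filter
correction, band integration and peak location.

A :class:`Spectrum` is a sampled optical curve (fluorescence emission,
synchronous fluorescence, absorbance, or circular dichroism) on a strictly
increasing wavelength grid, carrying the acquisition metadata the downstream
analyses need (excitation wavelength, synchronous offset, temperature,
protein and ligand concentrations).

The central operation is the whole-spectrum inner-filter correction

    F_corr(lambda) = F_obs(lambda) * 10**((A_ex + A(lambda)) / 2)

which undoes the attenuation of both the excitation beam and the emitted
light by an absorbing species in the cuvette.  When the ligand's absorption
band overlaps the emission band asymmetrically, the *uncorrected* spectra
show an apparent red shift of the emission maximum; applying the correction
over the entire spectrum removes it, which is why every quantitative
quenching analysis here insists on corrected spectra.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

SPECTRUM_KINDS = ("emission", "synchronous", "absorbance", "cd")

#: molar extinction coefficient of piperlongumine at its 326 nm band maximum
EPSILON_LIGAND = 18_700.0  # M^-1 cm^-1
LIGAND_ABS_PEAK_NM = 326.0


class SpectraError(ValueError):
    """Raised on malformed spectra files or invalid spectral operations."""


@dataclass
class Spectrum:
    """A sampled optical curve on a strictly increasing wavelength grid.

    Parameters
    ----------
    kind : {'emission', 'synchronous', 'absorbance', 'cd'}
        What the values mean: intensity (a.u.), absorbance (AU) or
        ellipticity (mdeg).
    wavelengths : array of float
        Grid in nm, strictly increasing, length >= 2.  Synchronous spectra
        are indexed by the *excitation* wavelength; the emission wavelength
        of each point is ``lambda_exc + meta['delta_nm']``.
    values : array of float
        Same length as ``wavelengths``.
    meta : dict
        Free-form metadata.  Recognised keys: ``excitation_nm`` (required
        for kind='emission'), ``delta_nm`` (required for
        kind='synchronous'), ``temperature_K``, ``protein_M``, ``ligand_M``,
        ``corrected`` (bool, set by the inner-filter correction),
        ``series_id``.
    """

    kind: str
    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise SpectraError(f"unknown spectrum kind {self.kind!r}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise SpectraError("wavelength grid must be 1-D with >= 2 points")
        if self.values.shape != self.wavelengths.shape:
            raise SpectraError("values and wavelengths must have equal length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if self.kind == "absorbance" and np.any(self.values < 0):
            raise SpectraError("absorbance values must be non-negative")
        if self.kind in ("emission", "synchronous") and np.any(self.values < 0):
            raise SpectraError(
                "fluorescence intensities must be non-negative "
                "(apply subtract_baseline, which clamps at zero)"
            )
        if self.kind == "emission" and "excitation_nm" not in self.meta:
            raise SpectraError("emission spectra require meta['excitation_nm']")
        if self.kind == "synchronous" and "delta_nm" not in self.meta:
            raise SpectraError("synchronous spectra require meta['delta_nm']")

    # -- convenience -------------------------------------------------------

    @property
    def is_corrected(self) -> bool:
        """Whether the inner-filter correction has been applied."""
        return bool(self.meta.get("corrected", False))

    def value_at(self, nm: float) -> float:
        """Linearly interpolated value at a wavelength inside the grid."""
        lam = self.wavelengths
        if not (lam[0] <= nm <= lam[-1]):
            raise SpectraError(
                f"wavelength {nm} nm outside grid [{lam[0]}, {lam[-1]}]"
            )
        return float(np.interp(nm, lam, self.values))

    def with_values(self, values, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.kind, self.wavelengths.copy(),
                        np.asarray(values, float), meta)


# ---------------------------------------------------------------------------
# file I/O: long-format delimited text with '#'-prefixed metadata header
# ---------------------------------------------------------------------------

_META_NUMERIC = ("excitation_nm", "delta_nm", "temperature_K",
                 "protein_M", "ligand_M")


def _parse_header(lines):
    """Parse '# key: value' header lines -> dict; values may be
    comma-separated lists (one entry per series, in order of appearance)."""
    meta = {}
    for lineno, line in lines:
        body = line.lstrip("#").strip()
        if not body:
            continue
        if ":" not in body:
            raise SpectraError(
                f"malformed header at line {lineno}: {line.rstrip()!r} "
                "(expected '# key: value')"
            )
        key, _, val = body.partition(":")
        meta[key.strip()] = val.strip()
    return meta


def _coerce_meta(raw: dict, n_series: int):
    """Expand the raw header into per-series metadata dictionaries."""
    per_series = [dict() for _ in range(n_series)]
    for key, val in raw.items():
        if key in _META_NUMERIC:
            parts = [p.strip() for p in val.split(",")]
            if len(parts) == 1:
                vals = [float(parts[0])] * n_series
            elif len(parts) == n_series:
                vals = [float(p) for p in parts]
            else:
                raise SpectraError(
                    f"header key {key!r} has {len(parts)} entries for "
                    f"{n_series} series"
                )
            for d, v in zip(per_series, vals):
                d[key] = v
        elif key == "corrected":
            flag = val.lower() in ("1", "true", "yes")
            for d in per_series:
                d[key] = flag
        elif key == "kind":
            continue
        else:
            for d in per_series:
                d[key] = val
    return per_series


def read_spectra(path, dialect: str | None = None) -> list[Spectrum]:
    """Read a long-format spectra file into a list of :class:`Spectrum`.

    The format is delimited text (comma or tab, auto-detected unless
    ``dialect`` is ``'csv'`` or ``'tsv'``) with columns
    ``series_id, wavelength_nm, value`` and a header block of
    ``# key: value`` lines.  ``kind`` is required; ``excitation_nm`` is
    required for emission spectra and ``delta_nm`` for synchronous ones.
    Numeric header values may be comma-separated lists giving one value per
    series (in order of first appearance).
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return _read_spectra_text(text, dialect, name=str(path))


def _read_spectra_text(text, dialect=None, name="<string>"):
    header_lines, data_lines = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            header_lines.append((lineno, line))
        elif line.strip():
            data_lines.append((lineno, line))
    raw_meta = _parse_header(header_lines)
    if "kind" not in raw_meta:
        raise SpectraError(f"{name}: header is missing '# kind: ...'")
    kind = raw_meta["kind"]
    if kind not in SPECTRUM_KINDS:
        raise SpectraError(f"{name}: unknown kind {kind!r}")
    if not data_lines:
        raise SpectraError(f"{name}: no data rows")

    if dialect is None:
        delim = "\t" if "\t" in data_lines[0][1] else ","
    else:
        delim = {"csv": ",", "tsv": "\t"}[dialect]

    series_order, series_data = [], {}
    start = 0
    first_fields = data_lines[0][1].split(delim)
    if first_fields[0].strip() == "series_id":
        start = 1  # optional column-header row
    for lineno, line in data_lines[start:]:
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != 3:
            raise SpectraError(
                f"{name}: line {lineno}: expected 3 columns, got {len(fields)}"
            )
        sid = fields[0]
        try:
            lam, val = float(fields[1]), float(fields[2])
        except ValueError as exc:
            raise SpectraError(f"{name}: line {lineno}: {exc}") from None
        if sid not in series_data:
            series_order.append(sid)
            series_data[sid] = ([], [])
        series_data[sid][0].append(lam)
        series_data[sid][1].append(val)

    per_series_meta = _coerce_meta(raw_meta, len(series_order))
    out = []
    for sid, meta in zip(series_order, per_series_meta):
        lam, val = series_data[sid]
        meta["series_id"] = sid
        out.append(Spectrum(kind, np.array(lam), np.array(val), meta))
    return out


def write_spectra(path, spectra: list[Spectrum], dialect: str = "csv") -> None:
    """Write spectra (all of one kind) in the long-format text layout."""
    if not spectra:
        raise SpectraError("nothing to write")
    kind = spectra[0].kind
    if any(s.kind != kind for s in spectra):
        raise SpectraError("all spectra in one file must share a kind")
    delim = {"csv": ",", "tsv": "\t"}[dialect]
    buf = io.StringIO()
    buf.write(f"# kind: {kind}\n")
    for key in _META_NUMERIC:
        if all(key in s.meta for s in spectra):
            vals = [s.meta[key] for s in spectra]
            buf.write(f"# {key}: "
                      + ",".join(repr(float(v)) for v in vals) + "\n")
    if all(s.meta.get("corrected") for s in spectra):
        buf.write("# corrected: true\n")
    buf.write(delim.join(("series_id", "wavelength_nm", "value")) + "\n")
    for i, s in enumerate(spectra):
        sid = str(s.meta.get("series_id", f"s{i}"))
        for lam, val in zip(s.wavelengths, s.values):
            buf.write(f"{sid}{delim}{float(lam)!r}{delim}{float(val)!r}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def subtract_baseline(sample: Spectrum, buffer: Spectrum) -> Spectrum:
    """Subtract the buffer-scatter baseline, clamping negatives at zero.

    Fluorescence cannot be negative; points driven below zero by the
    subtraction are clamped and the clamp count is logged.  The grids must
    be identical — no implicit resampling.
    """
    if (sample.wavelengths.shape != buffer.wavelengths.shape
            or not np.array_equal(sample.wavelengths, buffer.wavelengths)):
        raise SpectraError("baseline subtraction requires identical grids")
    diff = sample.values - buffer.values
    n_clamped = int(np.sum(diff < 0))
    if n_clamped:
        logger.info("subtract_baseline: clamped %d negative points to 0",
                    n_clamped)
    return sample.with_values(np.maximum(diff, 0.0))


def _absorbance_at(absorbance: Spectrum, nm_values) -> np.ndarray:
    """Linear interpolation of an absorbance spectrum; no extrapolation."""
    if absorbance.kind != "absorbance":
        raise SpectraError("expected an absorbance spectrum")
    lam = absorbance.wavelengths
    nm_values = np.atleast_1d(np.asarray(nm_values, float))
    if nm_values.min() < lam[0] or nm_values.max() > lam[-1]:
        raise SpectraError(
            f"absorbance grid [{lam[0]}, {lam[-1]}] nm does not cover "
            f"requested wavelengths [{nm_values.min()}, {nm_values.max()}] nm"
        )
    return np.interp(nm_values, lam, absorbance.values)


def inner_filter_correct(emission: Spectrum, absorbance: Spectrum,
                         exc_nm: float | None = None) -> Spectrum:
    """Whole-spectrum inner-filter correction of an emission spectrum.

    For every emission wavelength ``lam``::

        F_corr(lam) = F_obs(lam) * 10**((A(exc_nm) + A(lam)) / 2)

    with ``A`` the sample absorbance, linearly interpolated on its grid (no
    extrapolation).  With non-negative absorbances the correction factor is
    >= 1 everywhere.  The returned spectrum is flagged
    ``meta['corrected'] = True``, which the quenching analyses require.
    """
    if exc_nm is None:
        exc_nm = emission.meta.get("excitation_nm")
        if exc_nm is None:
            raise SpectraError("excitation wavelength required")
    a_ex = _absorbance_at(absorbance, exc_nm)[0]
    a_em = _absorbance_at(absorbance, emission.wavelengths)
    factor = 10.0 ** ((a_ex + a_em) / 2.0)
    return emission.with_values(emission.values * factor, corrected=True)


def inner_filter_correct_synchronous(sync: Spectrum, absorbance: Spectrum,
                                     delta_nm: float | None = None) -> Spectrum:
    """Inner-filter correction of a synchronous spectrum.

    Synchronous spectra are indexed by excitation wavelength; each point at
    ``lam_exc`` uses ``A(lam_exc)`` and ``A(lam_exc + delta_nm)``.
    """
    if delta_nm is None:
        delta_nm = sync.meta.get("delta_nm")
        if delta_nm is None:
            raise SpectraError("synchronous offset delta_nm required")
    a_ex = _absorbance_at(absorbance, sync.wavelengths)
    a_em = _absorbance_at(absorbance, sync.wavelengths + delta_nm)
    factor = 10.0 ** ((a_ex + a_em) / 2.0)
    return sync.with_values(sync.values * factor, corrected=True)


def integrate_band(s: Spectrum, lo_nm: float, hi_nm: float) -> float:
    """Trapezoidal band area between ``lo_nm`` and ``hi_nm`` (a.u.*nm).

    Endpoints falling between grid points are included by linear
    interpolation.  The window must lie within the recorded grid.
    """
    lam = s.wavelengths
    if not lo_nm < hi_nm:
        raise SpectraError("integration window requires lo < hi")
    if lo_nm < lam[0] or hi_nm > lam[-1]:
        raise SpectraError(
            f"window [{lo_nm}, {hi_nm}] outside grid [{lam[0]}, {lam[-1]}]"
        )
    inner = (lam > lo_nm) & (lam < hi_nm)
    grid = np.concatenate(([lo_nm], lam[inner], [hi_nm]))
    vals = np.interp(grid, lam, s.values)
    return float(np.trapezoid(vals, grid))


def peak_wavelength(s: Spectrum) -> float:
    """Wavelength of maximum value; ties go to the shortest wavelength.

    Plain grid argmax — resolution equals the grid spacing, so shift
    comparisons should allow +/- one grid step.  An all-zero spectrum emits
    a warning and returns the shortest wavelength.
    """
    if np.all(s.values == 0):
        warnings.warn("peak_wavelength: all-zero spectrum", stacklevel=2)
        return float(s.wavelengths[0])
    return float(s.wavelengths[int(np.argmax(s.values))])


# ---------------------------------------------------------------------------
# ligand absorbance from Beer-Lambert
# ---------------------------------------------------------------------------

def ligand_absorbance(concentration_M: float, wavelengths,
                      band_shape=None, epsilon: float = EPSILON_LIGAND,
                      path_cm: float = 1.0) -> Spectrum:
    """Ligand absorbance spectrum from Beer-Lambert, A = eps(lam) * c * l.

    ``band_shape(wavelengths)`` is a unit-normalised shape (1 at the band
    maximum); the default is the asymmetric piperlongumine band peaking at
    326 nm with ``epsilon`` = 18700 M^-1 cm^-1 there.  Used when a measured
    total-sample absorbance is not available.
    """
    from .bands import ligand_absorbance_shape
    if band_shape is None:
        band_shape = ligand_absorbance_shape
    wavelengths = np.asarray(wavelengths, float)
    values = epsilon * concentration_M * path_cm * band_shape(wavelengths)
    return Spectrum("absorbance", wavelengths, values,
                    {"ligand_M": concentration_M})
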