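import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from quenchbind import (Spectrum, inner_filter_correct,
                        inner_filter_correct_synchronous, integrate_band,
                        ligand_absorbance, peak_wavelength, read_spectra,
                        subtract_baseline, write_spectra)
from quenchbind.spectra import SpectraError, _read_spectra_text


def make_abs(lam, values):
    return Spectrum("absorbance", lam, values)


class TestSpectrumInvariants:
    def test_non_monotone_grid_rejected(self):
        with pytest.raises(SpectraError, match="increasing"):
            Spectrum("absorbance", [305, 304, 306], [1, 1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(SpectraError, match="equal length"):
            Spectrum("absorbance", [305, 306], [1, 1, 1])

    def test_negative_absorbance_rejected(self):
        with pytest.raises(SpectraError):
            Spectrum("absorbance", [305, 306], [1, -1])

    def test_emission_requires_excitation(self):
        with pytest.raises(SpectraError, match="excitation_nm"):
            Spectrum("emission", [305, 306], [1, 1])


class TestIO:
    def test_round_trip_two_series(self, tmp_path):
        lam = np.array([305.0, 306.0, 307.0])
        s1 = Spectrum("emission", lam, [1.0, 2.0, 3.0],
                      {"excitation_nm": 295.0, "ligand_M": 0.0,
                       "series_id": "a"})
        s2 = Spectrum("emission", lam, [4.0, 5.0, 6.0],
                      {"excitation_nm": 295.0, "ligand_M": 2e-6,
                       "series_id": "b"})
        path = tmp_path / "spec.csv"
        write_spectra(path, [s1, s2])
        back = read_spectra(path)
        assert len(back) == 2
        for orig, rd in zip([s1, s2], back):
            np.testing.assert_array_equal(orig.wavelengths, rd.wavelengths)
            np.testing.assert_array_equal(orig.values, rd.values)
            assert rd.meta["ligand_M"] == orig.meta["ligand_M"]
            assert rd.meta["excitation_nm"] == 295.0

    def test_missing_excitation_metadata_is_error(self):
        text = "# kind: emission\ns,305,1\ns,306,2\n"
        with pytest.raises(SpectraError, match="excitation_nm"):
            _read_spectra_text(text)

    def test_non_monotone_wavelengths_is_error(self):
        text = ("# kind: absorbance\ns,305,1\ns,304,1\ns,306,1\n")
        with pytest.raises(SpectraError, match="increasing"):
            _read_spectra_text(text)

    def test_malformed_header_names_line(self):
        text = "# kind: absorbance\n# garbage header\ns,305,1\ns,306,1\n"
        with pytest.raises(SpectraError, match="line 2"):
            _read_spectra_text(text)

    def test_tab_dialect_autodetected(self):
        text = "# kind: absorbance\ns\t305\t1\ns\t306\t2\n"
        (s,) = _read_spectra_text(text)
        assert s.values[1] == 2.0


class TestSubtractBaseline:
    def test_self_subtraction_is_zero(self):
        lam = [305.0, 306.0]
        s = Spectrum("emission", lam, [10.0, 20.0], {"excitation_nm": 295})
        out = subtract_baseline(s, s)
        np.testing.assert_array_equal(out.values, [0.0, 0.0])

    def test_zero_buffer_is_identity(self):
        lam = [305.0, 306.0]
        s = Spectrum("emission", lam, [10.0, 20.0], {"excitation_nm": 295})
        b = Spectrum("emission", lam, [0.0, 0.0], {"excitation_nm": 295})
        np.testing.assert_array_equal(subtract_baseline(s, b).values,
                                      s.values)

    def test_negative_clamped_to_zero(self):
        lam = [305.0, 306.0]
        s = Spectrum("emission", lam, [10.0, 20.0], {"excitation_nm": 295})
        b = Spectrum("emission", lam, [12.0, 5.0], {"excitation_nm": 295})
        np.testing.assert_array_equal(subtract_baseline(s, b).values,
                                      [0.0, 15.0])

    def test_grid_mismatch_rejected(self):
        s = Spectrum("emission", [305.0, 306.0], [1, 1],
                     {"excitation_nm": 295})
        b = Spectrum("emission", [305.0, 307.0], [1, 1],
                     {"excitation_nm": 295})
        with pytest.raises(SpectraError, match="identical grids"):
            subtract_baseline(s, b)


class TestInnerFilter:
    lam = np.arange(300.0, 411.0, 1.0)

    def emission(self, values=None):
        lam_e = np.arange(305.0, 401.0, 1.0)
        if values is None:
            values = np.ones(lam_e.size)
        return Spectrum("emission", lam_e, values, {"excitation_nm": 295.0})

    def test_zero_absorbance_identity(self):
        lam_a = np.arange(290.0, 411.0, 1.0)
        a = make_abs(lam_a, np.zeros(lam_a.size))
        em = self.emission()
        out = inner_filter_correct(em, a, 295.0)
        np.testing.assert_array_equal(out.values, em.values)
        assert out.is_corrected

    def test_unit_absorbance_gives_factor_ten(self):
        lam_a = np.arange(290.0, 411.0, 1.0)
        a = make_abs(lam_a, np.ones(lam_a.size))
        out = inner_filter_correct(self.emission(), a, 295.0)
        np.testing.assert_allclose(out.values, 10.0, rtol=1e-12)

    def test_uncovered_wavelength_is_error(self):
        a = make_abs(np.arange(305.0, 401.0), np.zeros(96))
        with pytest.raises(SpectraError, match="cover"):
            inner_filter_correct(self.emission(), a, 295.0)

    @given(st.lists(st.floats(0.0, 2.0), min_size=5, max_size=5),
           st.integers(0, 4), st.floats(0.001, 0.5))
    def test_monotone_in_absorbance(self, avals, idx, bump):
        """Raising any absorbance value never decreases any corrected
        intensity."""
        lam_a = np.array([290.0, 320.0, 350.0, 380.0, 410.0])
        em = self.emission()
        base = inner_filter_correct(em, make_abs(lam_a, avals), 295.0)
        more = list(avals)
        more[idx] += bump
        higher = inner_filter_correct(em, make_abs(lam_a, more), 295.0)
        assert np.all(higher.values >= base.values - 1e-15)

    def test_synchronous_indexing_convention(self):
        """A point at lambda_exc = 283 with offset 60 uses A(283) and
        A(343)."""
        lam_s = np.array([280.0, 283.0, 286.0])
        sync = Spectrum("synchronous", lam_s, np.ones(3), {"delta_nm": 60.0})
        lam_a = np.arange(240.0, 411.0, 1.0)
        avals = np.zeros(lam_a.size)
        avals[lam_a == 283.0] = 0.4
        avals[lam_a == 343.0] = 0.6
        out = inner_filter_correct_synchronous(sync, make_abs(lam_a, avals))
        np.testing.assert_allclose(out.values[1], 10.0 ** ((0.4 + 0.6) / 2))
        np.testing.assert_allclose(out.values[0], 1.0)

    def test_synchronous_zero_absorbance_identity(self):
        lam_s = np.array([280.0, 283.0, 286.0])
        sync = Spectrum("synchronous", lam_s, [1.0, 2.0, 1.0],
                        {"delta_nm": 60.0})
        lam_a = np.arange(240.0, 411.0, 1.0)
        out = inner_filter_correct_synchronous(
            sync, make_abs(lam_a, np.zeros(lam_a.size)))
        np.testing.assert_array_equal(out.values, sync.values)


class TestIntegrateBand:
    def test_constant_over_window(self):
        lam = np.arange(300.0, 411.0, 1.0)
        s = Spectrum("emission", lam, np.ones(lam.size),
                     {"excitation_nm": 295})
        assert integrate_band(s, 305.0, 400.0) == pytest.approx(95.0)

    def test_zero_spectrum(self):
        lam = np.arange(300.0, 411.0, 1.0)
        s = Spectrum("emission", lam, np.zeros(lam.size),
                     {"excitation_nm": 295})
        assert integrate_band(s, 305.0, 400.0) == 0.0

    def test_triangle_area(self):
        lam = np.arange(300.0, 411.0, 1.0)
        vals = np.interp(lam, [305.0, 340.0, 375.0], [0.0, 1.0, 0.0])
        s = Spectrum("emission", lam, vals, {"excitation_nm": 295})
        assert integrate_band(s, 305.0, 375.0) == pytest.approx(35.0)

    def test_window_outside_grid_is_error(self):
        lam = np.arange(305.0, 401.0, 1.0)
        s = Spectrum("emission", lam, np.ones(lam.size),
                     {"excitation_nm": 295})
        with pytest.raises(SpectraError, match="outside grid"):
            integrate_band(s, 300.0, 400.0)

    @given(st.floats(310.0, 390.0), st.floats(0.1, 5.0))
    def test_additive_over_windows_and_linear(self, mid, scale):
        lam = np.arange(305.0, 401.0, 1.0)
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 10, lam.size)
        s = Spectrum("emission", lam, vals, {"excitation_nm": 295})
        total = integrate_band(s, 305.0, 400.0)
        split = (integrate_band(s, 305.0, mid)
                 + integrate_band(s, mid, 400.0))
        assert split == pytest.approx(total, rel=1e-9)
        scaled = s.with_values(vals * scale)
        assert integrate_band(scaled, 305.0, 400.0) == pytest.approx(
            scale * total, rel=1e-9)


class TestPeakWavelength:
    def test_gaussian_band_peak(self):
        lam = np.arange(305.0, 401.0, 1.0)
        vals = np.exp(-((lam - 340.0) ** 2) / 200.0)
        s = Spectrum("emission", lam, vals, {"excitation_nm": 295})
        assert peak_wavelength(s) == 340.0

    def test_tie_breaks_to_shortest_wavelength(self):
        lam = np.arange(330.0, 351.0, 1.0)
        vals = np.zeros(lam.size)
        vals[lam == 338.0] = 5.0
        vals[lam == 342.0] = 5.0
        s = Spectrum("emission", lam, vals, {"excitation_nm": 295})
        assert peak_wavelength(s) == 338.0

    def test_all_zero_warns_and_returns_shortest(self):
        lam = np.arange(305.0, 311.0, 1.0)
        s = Spectrum("emission", lam, np.zeros(lam.size),
                     {"excitation_nm": 295})
        with pytest.warns(UserWarning, match="all-zero"):
            assert peak_wavelength(s) == 305.0


class TestShiftElimination:
    """The false red shift: asymmetric ligand absorbance drags the apparent
    emission maximum to the red; whole-spectrum correction restores it."""

    def test_observed_red_shifted_corrected_restored(self, titrations):
        for series in titrations:
            assert peak_wavelength(series.spectra[-1]) > 340.0
            corr = series.corrected()
            for s in corr.spectra:
                assert abs(peak_wavelength(s) - 340.0) <= 1.0

    def test_correction_recovers_true_band(self, titrations):
        """Spectra built as F_true * 10^-(A_ex+A_em)/2 come back to F_true
        within round-off, so the peaks coincide exactly."""
        series = titrations[1]
        corr = series.corrected()
        for c, t in zip(corr.spectra, series.true_spectra):
            np.testing.assert_allclose(c.values, t.values, rtol=1e-12,
                                       atol=1e-12 * t.values.max())
            assert peak_wavelength(c) == peak_wavelength(t)


def test_ligand_absorbance_beer_lambert_scaling():
    lam = np.arange(240.0, 501.0, 1.0)
    a1 = ligand_absorbance(16e-6, lam)
    a2 = ligand_absorbance(32e-6, lam)
    np.testing.assert_allclose(a2.values, 2 * a1.values, rtol=1e-12)
    assert a1.value_at(326.0) == pytest.approx(18700 * 16e-6, rel=1e-6)
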