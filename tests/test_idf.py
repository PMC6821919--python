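import numpy as np
import pytest

from quenchbind import (BindingDensityCurve, GroundTruth, TitrationSeries,
                        binding_density_curve, hill_fit, match_levels,
                        quench_percentage, scatchard)
from quenchbind.idf import IDFError
from tests.conftest import flat_spectrum

TRUE_K = (2.3e5, 1.3e5)
TRUE_W = (2.93, 8.15)


class TestQuenchPercentage:
    @pytest.mark.parametrize("fobs,ffree,expected", [
        (100.0, 100.0, 0.0),
        (50.0, 100.0, 50.0),
        (0.0, 100.0, 100.0),
    ])
    def test_values(self, fobs, ffree, expected):
        assert quench_percentage(fobs, ffree) == expected

    def test_non_positive_reference_rejected(self):
        with pytest.raises(IDFError):
            quench_percentage(1.0, 0.0)


def series_with_quench(protein, ligand, dF_values, F0=100.0):
    """Titration whose quench percentages are exactly dF_values at the
    positive-ligand points (flat corrected spectra)."""
    spectra = [flat_spectrum(F0, corrected=True)]
    for dF in dF_values:
        spectra.append(flat_spectrum(F0 * (1 - dF / 100.0), corrected=True))
    lig = np.concatenate([[0.0], ligand])
    return TitrationSeries(protein, 288.0, lig, spectra)


class TestMatchLevels:
    def test_exact_mass_conservation_line(self):
        """A level hit exactly by all three ladders: totals (2, 3, 5) uM at
        protein (2, 4, 8) uM give slope 0.5, intercept 1 uM, r^2 = 1."""
        level = 20.0
        series_set = [
            series_with_quench(2e-6, [1e-6, 2e-6, 4e-6], [5.0, level, 40.0]),
            series_with_quench(4e-6, [1e-6, 3e-6, 6e-6], [5.0, level, 40.0]),
            series_with_quench(8e-6, [2e-6, 5e-6, 9e-6], [5.0, level, 40.0]),
        ]
        (lv,) = match_levels(series_set, levels=[level], mode="intensity")
        assert lv.sum_nu == pytest.approx(0.5, rel=1e-9)
        assert lv.free_ligand == pytest.approx(1e-6, rel=1e-9)
        assert lv.r_squared == pytest.approx(1.0)
        assert lv.accepted

    def test_single_protein_concentration_rejected(self):
        s = series_with_quench(2e-6, [1e-6, 2e-6], [5.0, 10.0])
        with pytest.raises(IDFError, match=">= 2"):
            match_levels([s], levels=5)

    def test_non_monotone_quench_beyond_tolerance_is_error(self):
        bad = series_with_quench(2e-6, [1e-6, 2e-6, 4e-6],
                                 [20.0, 5.0, 40.0])
        ok = series_with_quench(4e-6, [1e-6, 2e-6, 4e-6],
                                [5.0, 10.0, 40.0])
        with pytest.raises(IDFError, match="2e-06"):
            match_levels([bad, ok], levels=5, mode="intensity")

    def test_recovered_levels_satisfy_forward_model(self, truth,
                                                    idf_pipeline):
        """Each accepted level's (L_free, sum_nu) pair lies on the
        generator's occupancy curve, up to ladder-interpolation error
        (within 0.1 of 2 total sites; the steep second transition dominates
        the piecewise-linear inversion error on the 2 uM ladder)."""
        _, curve, _ = idf_pipeline
        nu_true = truth.occupancy(curve.free_ligand)
        np.testing.assert_allclose(curve.sum_nu, nu_true, atol=0.1)

    def test_negative_intercept_levels_flagged(self):
        # a level where L_total barely depends on protein, forced through
        # origin-crossing noise: intercept < 0 must be rejected, not used
        series_set = [
            series_with_quench(2e-6, [1e-6, 2e-6, 4e-6], [5.0, 20.0, 40.0]),
            series_with_quench(4e-6, [0.4e-6, 2.2e-6, 4e-6], [5.0, 20.0, 40.0]),
            series_with_quench(8e-6, [2e-6, 6e-6, 9e-6], [5.0, 20.0, 40.0]),
        ]
        levels = match_levels(series_set, levels=[5.0], mode="intensity",
                              r2_threshold=0.0)
        rejected = [lv for lv in levels if not lv.accepted]
        for lv in rejected:
            assert "negative" in lv.reject_reason


class TestScatchard:
    def test_langmuir_is_non_cooperative(self):
        """Scatchard of a 1-site Langmuir is a straight declining line."""
        k = 1e5
        lf = np.geomspace(1e-6, 5e-5, 5)
        curve = BindingDensityCurve(lf, k * lf / (1 + k * lf))
        assert scatchard(curve).verdict == "non-cooperative"

    def test_hill_w_above_one_is_positive_cooperative(self, truth):
        lf = np.geomspace(1e-6, 2e-5, 12)
        curve = BindingDensityCurve(lf, truth.occupancy(lf))
        assert scatchard(curve).verdict == "positive-cooperative"

    def test_too_few_points_is_error(self):
        curve = BindingDensityCurve([1e-6, 2e-6, 3e-6], [0.1, 0.2, 0.3])
        with pytest.raises(IDFError, match=">= 4"):
            scatchard(curve)

    def test_w_equal_one_never_positive_cooperative(self):
        """Specificity: no Langmuir sampling may be called cooperative."""
        for k in (1e4, 1e5, 1e6):
            for n_pts in (5, 9, 15):
                lf = np.geomspace(0.05 / k, 20 / k, n_pts)
                curve = BindingDensityCurve(lf, k * lf / (1 + k * lf))
                assert scatchard(curve).verdict != "positive-cooperative"


class TestHillFit:
    def test_forward_curve_recovers_two_classes(self, truth):
        """30 noiseless log-spaced points from the two-class ground truth:
        model selection picks 2 classes and recovers both constants."""
        lf = np.geomspace(2e-6, 1.3e-5, 30)
        curve = BindingDensityCurve(lf, truth.occupancy(lf))
        res = hill_fit(curve, max_classes=3)
        assert res.n_classes == 2
        assert res.classes[0].k == pytest.approx(TRUE_K[0], rel=0.05)
        assert res.classes[1].k == pytest.approx(TRUE_K[1], rel=0.05)
        assert res.classes[0].w == pytest.approx(TRUE_W[0], rel=0.01)
        assert res.classes[1].w == pytest.approx(TRUE_W[1], rel=0.01)

    def test_single_langmuir_exact_recovery(self):
        k = 1e5
        lf = np.geomspace(1e-6, 5e-5, 12)
        curve = BindingDensityCurve(lf, k * lf / (1 + k * lf))
        res = hill_fit(curve, max_classes=3)
        assert res.n_classes == 1
        assert res.classes[0].k == pytest.approx(k, rel=1e-6)
        assert res.classes[0].w == pytest.approx(1.0, abs=1e-6)

    def test_occupancy_value_at_reciprocal_k1(self, truth):
        """At L_free = 1/k1 the first class contributes exactly 1/2."""
        assert truth.occupancy(1 / 2.3e5) == pytest.approx(0.509472,
                                                           abs=1e-4)

    def test_prediction_monotone_and_saturating(self, truth):
        lf = np.geomspace(2e-6, 1.3e-5, 20)
        res = hill_fit(BindingDensityCurve(lf, truth.occupancy(lf)),
                       max_classes=2)
        grid = np.geomspace(1e-8, 1e-2, 200)
        pred = res.predict(grid)
        assert np.all(np.diff(pred) > -1e-12)
        assert pred[-1] <= res.total_sites + 1e-9
        assert pred[-1] == pytest.approx(res.total_sites, rel=1e-3)

    def test_invalid_max_classes_rejected(self, truth):
        lf = np.geomspace(1e-6, 1e-5, 10)
        curve = BindingDensityCurve(lf, truth.occupancy(lf))
        with pytest.raises(IDFError, match="max_classes"):
            hill_fit(curve, max_classes=0)


class TestEndToEnd:
    def test_noiseless_pipeline_recovery(self, idf_pipeline):
        """Generator -> correction -> quench levels -> mass-conservation
        regression -> Hill fit recovers the two-class truth: k within 5%,
        affinity indexes within 10%."""
        _, _, hill = idf_pipeline
        assert hill.n_classes == 2
        assert hill.classes[0].k == pytest.approx(TRUE_K[0], rel=0.05)
        assert hill.classes[1].k == pytest.approx(TRUE_K[1], rel=0.05)
        assert hill.classes[0].w == pytest.approx(TRUE_W[0], rel=0.10)

    def test_pipeline_scatchard_is_convex(self, idf_pipeline):
        _, curve, _ = idf_pipeline
        assert scatchard(curve).verdict == "positive-cooperative"
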