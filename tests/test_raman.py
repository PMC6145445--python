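"""Raman pipeline: smoothing, baseline, peaks, MSC, filtering, PLS-DA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodulescope import raman, synth
from nodulescope.datatypes import RamanSpectrum
from nodulescope.raman import (
    FeatureConfig,
    NoPeakError,
    SpectralFeatures,
    correct_baseline,
    cross_validate_plsda,
    extract_features,
    filter_by_po4_area,
    fit_peak,
    fit_plsda,
    group_mean_and_difference,
    msc_normalize,
    smooth_savgol,
    venetian_blinds_folds,
)

SQRT_2PI = np.sqrt(2 * np.pi)


def spectrum(x, y, sid="s", group=None):
    return RamanSpectrum(np.asarray(x, float), np.asarray(y, float), sid, group)


class TestSavgol:
    def test_reproduces_quadratic_exactly(self):
        x = np.arange(600.0, 700.0)
        y = 3 * x**2 - x + 2
        out = smooth_savgol(spectrum(x, y))
        np.testing.assert_allclose(out.intensities, y, rtol=1e-10)

    def test_constant_unchanged(self):
        x = np.arange(600.0, 650.0)
        out = smooth_savgol(spectrum(x, np.full_like(x, 7.0)))
        np.testing.assert_allclose(out.intensities, 7.0)

    def test_interior_point_equals_local_least_squares_fit(self):
        """Independent oracle: a degree-2 polynomial fitted over the 5-point
        neighbourhood, evaluated at the centre; equivalently the classic
        (-3, 12, 17, 12, -3)/35 kernel."""
        rng = np.random.default_rng(4)
        x = np.arange(600.0, 640.0)
        y = rng.normal(size=x.size)
        out = smooth_savgol(spectrum(x, y))
        i = 17
        coeffs = np.polyfit(x[i - 2 : i + 3], y[i - 2 : i + 3], 2)
        oracle = np.polyval(coeffs, x[i])
        kernel = np.array([-3, 12, 17, 12, -3]) / 35.0
        assert out.intensities[i] == pytest.approx(oracle, rel=1e-10)
        assert out.intensities[i] == pytest.approx(kernel @ y[i - 2 : i + 3])

    @pytest.mark.parametrize("window", [4, 101])
    def test_bad_windows_rejected(self, window):
        x = np.arange(600.0, 650.0)
        with pytest.raises(ValueError):
            smooth_savgol(spectrum(x, x), window_points=window)


class TestBaseline:
    def test_pure_degree5_polynomial_removed(self, axis):
        u = np.linspace(-1, 1, axis.size)
        y = 100 + 30 * u - 50 * u**3 + 20 * u**5
        corrected, baseline = correct_baseline(spectrum(axis, y))
        rng = y.max() - y.min()
        assert np.abs(corrected.intensities).max() < 1e-6 * rng
        np.testing.assert_allclose(baseline.intensities, y, rtol=1e-6)

    def test_polynomial_plus_gaussian_preserves_area(self, axis):
        u = np.linspace(-1, 1, axis.size)
        poly = 200 - 80 * u + 40 * u**2 + 15 * u**5
        true_area = 100.0 * 5.0 * SQRT_2PI
        y = poly + 100.0 * np.exp(-((axis - 960.0) ** 2) / (2 * 5.0**2))
        corrected, _ = correct_baseline(spectrum(axis, y))
        fit = fit_peak(corrected, (930.0, 990.0))
        assert fit.area == pytest.approx(true_area, rel=0.01)

    def test_all_zero_input_gives_zero_baseline(self, axis):
        corrected, baseline = correct_baseline(spectrum(axis, np.zeros_like(axis)))
        assert np.all(corrected.intensities == 0)
        assert np.all(baseline.intensities == 0)

    def test_additive_offset_commutes(self, axis):
        """Shifting a spectrum by a constant shifts the fitted baseline by
        the same constant, leaving the corrected signal unchanged."""
        u = np.linspace(-1, 1, axis.size)
        y = 50 + 20 * u**2 + 80 * np.exp(-((axis - 960.0) ** 2) / 50.0)
        c1, _ = correct_baseline(spectrum(axis, y))
        c2, _ = correct_baseline(spectrum(axis, y + 500.0))
        np.testing.assert_allclose(c1.intensities, c2.intensities, atol=1e-6)

    def test_too_short_spectrum_rejected(self):
        x = np.arange(600.0, 606.0)
        with pytest.raises(ValueError):
            correct_baseline(spectrum(x, x))


class TestFitPeak:
    def test_noiseless_gaussian_recovered_exactly(self, axis):
        y = 100.0 * np.exp(-((axis - 960.0) ** 2) / (2 * 5.0**2))
        fit = fit_peak(spectrum(axis, y), (930.0, 990.0))
        assert fit.center == pytest.approx(960.0, abs=1e-6)
        assert fit.area == pytest.approx(100.0 * 5.0 * SQRT_2PI, rel=1e-6)
        assert fit.area == pytest.approx(1253.314, rel=1e-4)

    def test_shifted_center_recovered(self, axis):
        y = 80.0 * np.exp(-((axis - 962.1) ** 2) / (2 * 6.0**2))
        fit = fit_peak(spectrum(axis, y), (930.0, 990.0))
        assert fit.center == pytest.approx(962.1, abs=1e-6)

    def test_flat_window_raises_no_peak(self, axis):
        with pytest.raises(NoPeakError):
            fit_peak(spectrum(axis, np.zeros_like(axis)), (930.0, 990.0))

    def test_offset_absorbed_when_enabled(self, axis):
        y = 5.0 + 100.0 * np.exp(-((axis - 960.0) ** 2) / (2 * 5.0**2))
        fit = fit_peak(spectrum(axis, y), (930.0, 990.0), with_offset=True)
        assert fit.offset == pytest.approx(5.0, abs=1e-6)
        assert fit.area == pytest.approx(100.0 * 5.0 * SQRT_2PI, rel=1e-6)

    def test_window_too_small_rejected(self, axis):
        y = np.ones_like(axis)
        with pytest.raises(ValueError, match="8 points"):
            fit_peak(spectrum(axis, y), (960.0, 963.0))


class TestMsc:
    def _set(self, axis):
        base = 100.0 * np.exp(-((axis - 960.0) ** 2) / 50.0) + 30.0 * np.exp(
            -((axis - 1660.0) ** 2) / 500.0
        )
        return base

    def test_reference_itself_unchanged(self, axis):
        base = self._set(axis)
        ref = spectrum(axis, base, "ref")
        [res] = msc_normalize([spectrum(axis, base, "a")], reference=ref)
        assert res.slope == pytest.approx(1.0)
        assert res.offset == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.corrected.intensities, base)

    def test_affine_distortion_recovered(self, axis):
        base = self._set(axis)
        ref = spectrum(axis, base, "ref")
        [res] = msc_normalize([spectrum(axis, 2.0 * base + 3.0, "a")], reference=ref)
        assert res.slope == pytest.approx(2.0)
        assert res.offset == pytest.approx(3.0)
        np.testing.assert_allclose(res.corrected.intensities, base, atol=1e-9)

    def test_idempotent_against_fixed_reference(self, axis):
        rng = np.random.default_rng(0)
        base = self._set(axis)
        ref = spectrum(axis, base, "ref")
        y = 1.7 * base + 12.0 + rng.normal(0, 1, axis.size)
        [once] = msc_normalize([spectrum(axis, y, "a")], reference=ref)
        [twice] = msc_normalize([once.corrected], reference=ref)
        np.testing.assert_allclose(
            twice.corrected.intensities, once.corrected.intensities, atol=1e-9
        )

    def test_zero_variance_reference_rejected(self, axis):
        flat = spectrum(axis, np.ones_like(axis), "flat")
        with pytest.raises(ValueError, match="variance"):
            msc_normalize([flat], reference=flat)


class TestFeatures:
    def test_known_areas_give_ratio(self, axis):
        y = 100.0 * np.exp(-((axis - 960.0) ** 2) / (2 * 5.0**2)) + 50.0 * np.exp(
            -((axis - 1660.0) ** 2) / (2 * 5.0**2)
        )
        f = extract_features(spectrum(axis, y))
        assert f.mineral_to_matrix == pytest.approx(2.0, rel=0.01)
        assert f.included

    def test_global_rescale_with_msc_keeps_ratio(self, axis, bone_truth):
        s = synth.generate_raman_spectrum(bone_truth, sample_id="a")
        sm, _ = correct_baseline(smooth_savgol(s))
        scaled = sm.replace_intensities(3.0 * sm.intensities)
        ref = sm
        [r1] = msc_normalize([sm], reference=ref)
        [r2] = msc_normalize([scaled], reference=ref)
        f1 = extract_features(r1.corrected)
        f2 = extract_features(r2.corrected)
        assert f2.mineral_to_matrix == pytest.approx(f1.mineral_to_matrix, rel=1e-6)

    def test_missing_amide_band_flags_ratio(self, axis):
        y = 100.0 * np.exp(-((axis - 960.0) ** 2) / (2 * 5.0**2))
        with pytest.raises(NoPeakError):
            extract_features(spectrum(axis, y))


class TestFilter:
    def test_strict_less_than_semantics(self):
        feats = [
            SpectralFeatures(str(a), None, float(a), 960.0, 1.0, 1.0, True)
            for a in (499, 500, 501)
        ]
        kept, excluded = filter_by_po4_area(feats, threshold=500.0)
        assert {f.sample_id for f in kept} == {"500", "501"}
        assert {f.sample_id for f in excluded} == {"499"}

    def test_all_below_threshold(self):
        feats = [SpectralFeatures("a", None, 10.0, 960.0, 1.0, 1.0, False)]
        kept, excluded = filter_by_po4_area(feats)
        assert kept == [] and len(excluded) == 1

    def test_zero_threshold_keeps_all(self):
        feats = [
            SpectralFeatures(str(i), None, float(i), 960.0, 1.0, 1.0, True)
            for i in range(5)
        ]
        kept, excluded = filter_by_po4_area(feats, threshold=0.0)
        assert len(kept) == 5 and excluded == []

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=0, max_size=40))
    def test_conservation_and_idempotence(self, areas):
        feats = [
            SpectralFeatures(str(i), None, a, 960.0, 1.0, 1.0, True)
            for i, a in enumerate(areas)
        ]
        kept, excluded = filter_by_po4_area(feats)
        assert len(kept) + len(excluded) == len(feats)
        kept2, excluded2 = filter_by_po4_area(kept)
        assert kept2 == kept and excluded2 == []


class TestGroupDifference:
    def test_identical_groups_difference_zero(self, axis, bone_truth):
        sps = [
            synth.generate_raman_spectrum(bone_truth, sample_id=f"s{i}", group=g)
            for i, g in enumerate(["a", "a", "b", "b"])
        ]
        _, _, diff = group_mean_and_difference(sps, "a", "b")
        np.testing.assert_allclose(diff.intensities, 0.0, atol=1e-9)

    def test_singletons_difference_exact(self, axis):
        a = spectrum(axis, np.sin(axis / 50.0), "a", "ga")
        b = spectrum(axis, np.cos(axis / 50.0), "b", "gb")
        _, _, diff = group_mean_and_difference([a, b], "ga", "gb")
        np.testing.assert_array_equal(
            diff.intensities, a.intensities - b.intensities
        )

    def test_position_shift_produces_derivative_lobes(self, axis):
        """Analytic oracle: the difference of two Gaussians shifted by +1
        cm^-1 has a positive lobe above the centre and a negative lobe
        below (for the group with the higher position, minus control)."""
        g = lambda c: np.exp(-((axis - c) ** 2) / (2 * 6.0**2))
        shifted = spectrum(axis, g(961.0), "s", "treated")
        control = spectrum(axis, g(960.0), "c", "control")
        _, _, diff = group_mean_and_difference([shifted, control], "treated", "control")
        upper = (axis > 960.5) & (axis < 975)
        lower = (axis > 945) & (axis < 960.4)
        assert diff.intensities[upper].max() > 0
        assert diff.intensities[lower].min() < 0
        analytic = g(961.0) - g(960.0)
        np.testing.assert_allclose(diff.intensities, analytic, atol=1e-12)

    def test_empty_group_rejected(self, axis):
        a = spectrum(axis, axis, "a", "ga")
        with pytest.raises(ValueError, match="empty"):
            group_mean_and_difference([a], "ga", "gb")


class TestPlsda:
    def test_separable_classes_fit_perfectly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 30)) * 0.01
        X[:10, 0] += 10.0
        labels = ["a"] * 10 + ["b"] * 10
        model = fit_plsda(X, labels, n_components=2)
        assigned, classified = model.classify(X)
        assert classified.all()
        assert [model.classes[i] for i in assigned] == labels

    def test_full_rank_components_equal_least_squares(self):
        """Independent oracle: with components spanning the full column
        rank, PLS2 fitted values equal the OLS fit of the class codes."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 6))
        labels = ["a"] * 6 + ["b"] * 6
        model = fit_plsda(X, labels, n_components=6)
        pred = model.predict_coded(X)
        Y = np.zeros((12, 2))
        Y[:6, 0] = 1.0
        Y[6:, 1] = 1.0
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)
        ols = Y.mean(axis=0) + Xc @ beta
        assert np.abs(pred - ols).max() < 1e-8

    def test_single_class_rejected(self):
        X = np.eye(8)
        with pytest.raises(ValueError, match="class"):
            fit_plsda(X, ["a"] * 8, n_components=2)

    def test_fold_partition_properties(self):
        folds = venetian_blinds_folds(10, 10)
        assert all(f.size == 1 for f in folds)  # leave-one-out pattern
        folds = venetian_blinds_folds(23, 10)
        joined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(joined, np.arange(23))
        for i, a in enumerate(folds):
            for b in folds[i + 1 :]:
                assert np.intersect1d(a, b).size == 0

    def test_too_many_splits_rejected(self):
        with pytest.raises(ValueError):
            venetian_blinds_folds(5, 10)

    def test_cv_report_rates_in_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 25))
        X[:20] += 4.0
        labels = ["a"] * 20 + ["b"] * 20
        order = rng.permutation(40)
        rep = cross_validate_plsda(
            X[order], [labels[i] for i in order], n_components=3
        )
        vals = rep.table[["fraction_classified", "sensitivity", "specificity"]]
        assert ((vals >= 0) & (vals <= 1)).all().all()
        err = rep.table["classification_error"]
        sens, spec = rep.table["sensitivity"], rep.table["specificity"]
        np.testing.assert_allclose(err, 1 - (sens + spec) / 2)
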