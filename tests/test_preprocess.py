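"""Normalization, mean spectrum, feature lists and image filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmsi.io import MSImageDataset, PixelSpectrum
from lipidmsi.preprocess import (
    FeatureList,
    deisotope,
    extract_feature_table,
    feature_image,
    hotspot_clip,
    mean_spectrum,
    median_denoise,
    normalize_dataset,
    refine_feature_list,
    remove_background_features,
    rms_factor,
    sliding_window_peaks,
)


def _spec(mz, inten, x=1, y=1):
    return PixelSpectrum(np.asarray(mz, float), np.asarray(inten, float), x, y)


def _ds(spectra, shape):
    return MSImageDataset(list(spectra), shape=shape)


class TestRmsNormalization:
    def test_three_four_example(self):
        s = _spec([100.0, 200.0], [3.0, 4.0])
        assert rms_factor(s) == pytest.approx(np.sqrt(12.5), abs=1e-5)
        norm = normalize_dataset(_ds([s], (1, 1))).spectra[0]
        np.testing.assert_allclose(norm.intensity, [0.84853, 1.13137], atol=1e-5)

    def test_constant_spectrum_becomes_ones(self):
        s = _spec([100.0, 200.0, 300.0], [7.0, 7.0, 7.0])
        norm = normalize_dataset(_ds([s], (1, 1))).spectra[0]
        np.testing.assert_allclose(norm.intensity, 1.0)

    def test_all_zero_pixel_kept_as_zeros(self):
        s = _spec([100.0, 200.0], [0.0, 0.0])
        norm = normalize_dataset(_ds([s], (1, 1))).spectra[0]
        np.testing.assert_array_equal(norm.intensity, 0.0)

    def test_normalized_rms_is_one(self, rng):
        s = _spec(np.sort(rng.uniform(150, 900, 20)), rng.uniform(0.1, 50, 20))
        norm = normalize_dataset(_ds([s], (1, 1))).spectra[0]
        assert rms_factor(norm) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 100))
    def test_scale_invariance(self, scale, seed):
        r = np.random.default_rng(seed)
        mz = np.sort(r.uniform(150, 900, 10))
        inten = r.uniform(0.1, 10, 10)
        a = normalize_dataset(_ds([_spec(mz, inten)], (1, 1))).spectra[0]
        b = normalize_dataset(_ds([_spec(mz, inten * scale)], (1, 1))).spectra[0]
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-10)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            rms_factor(_spec([], []))


class TestMeanSpectrum:
    def test_single_pixel_regridded_identity(self):
        s = _spec([500.0, 600.0], [10.0, 20.0])
        mean = mean_spectrum([_ds([s], (1, 1))], bin_ppm=1.0)
        assert mean.intensity.sum() == pytest.approx(30.0)
        np.testing.assert_allclose(mean.mz, [500.0, 600.0], rtol=2e-6)

    def test_duplicated_dataset_idempotent(self):
        d = _ds([_spec([500.0, 600.0], [10.0, 20.0])], (1, 1))
        one = mean_spectrum([d])
        two = mean_spectrum([d, d])
        np.testing.assert_allclose(one.intensity, two.intensity)

    def test_disjoint_peaks_average_to_half(self):
        d = _ds(
            [_spec([500.0], [10.0], 1, 1), _spec([600.0], [30.0], 2, 1)],
            (1, 2),
        )
        mean = mean_spectrum([d])
        np.testing.assert_allclose(sorted(mean.intensity), [5.0, 15.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_spectrum([])


class TestSlidingWindowPeaks:
    def test_two_isolated_peaks(self):
        mean = _spec([496.3398, 500.0], [100.0, 50.0])
        feats = sliding_window_peaks(mean, 3.0, min_intensity=10.0)
        assert len(feats) == 2

    def test_flat_spectrum_no_features(self):
        mean = _spec([500.0], [0.0])
        assert len(sliding_window_peaks(mean, 3.0, min_intensity=1.0)) == 0

    def test_close_apexes_higher_wins(self):
        m = 500.0
        mean = _spec([m, m * (1 + 2e-6)], [80.0, 100.0])
        feats = sliding_window_peaks(mean, 3.0, min_intensity=1.0)
        assert len(feats) == 1
        # exhaustive scan oracle: the global maximum survives
        assert feats.mz[0] == pytest.approx(m * (1 + 2e-6))

    def test_threshold_drops_small_peaks(self):
        mean = _spec([400.0, 500.0], [5.0, 100.0])
        feats = sliding_window_peaks(mean, 3.0, min_intensity=10.0)
        assert len(feats) == 1 and feats.mz[0] == pytest.approx(500.0)


class TestExtractFeatureTable:
    feats = FeatureList(np.array([500.0]), np.array([3.0]))

    def test_peak_at_apex(self):
        d = _ds([_spec([500.0], [7.0])], (1, 1))
        assert extract_feature_table(d, self.feats)[0, 0] == pytest.approx(7.0)

    def test_peak_outside_window_is_zero(self):
        d = _ds([_spec([500.0 * (1 + 5e-6)], [7.0])], (1, 1))
        assert extract_feature_table(d, self.feats)[0, 0] == 0.0

    def test_two_peaks_inside_window_sum(self):
        d = _ds([_spec([500.0 * (1 - 1e-6), 500.0 * (1 + 1e-6)], [3.0, 4.0])], (1, 1))
        assert extract_feature_table(d, self.feats)[0, 0] == pytest.approx(7.0)

    def test_windows_half_open_at_upper_edge(self):
        lo, hi = self.feats.windows()
        d = _ds([_spec([hi[0]], [5.0])], (1, 1))
        assert extract_feature_table(d, self.feats)[0, 0] == 0.0

    def test_additive_over_disjoint_windows(self, rng):
        feats = FeatureList(np.array([500.0, 600.0]), np.array([3.0]))
        mz = np.sort(np.concatenate([500.0 * (1 + rng.uniform(-2e-6, 2e-6, 3)),
                                     600.0 * (1 + rng.uniform(-2e-6, 2e-6, 3))]))
        inten = rng.uniform(1, 10, 6)
        d = _ds([_spec(mz, inten)], (1, 1))
        tab = extract_feature_table(d, feats)
        assert tab.sum() == pytest.approx(inten.sum())


class TestImageFilters:
    def test_all_equal_image_unchanged_by_clip(self):
        img = np.full((10, 10), 3.0)
        np.testing.assert_array_equal(hotspot_clip(img, 0.99), img)

    def test_extreme_pixel_clipped_to_percentile(self, rng):
        img = rng.uniform(0, 1, (10, 10))
        img[5, 5] = 100.0
        clipped = hotspot_clip(img, 0.99)
        assert clipped[5, 5] == pytest.approx(np.quantile(img, 0.99))
        ranks = np.argsort(img.ravel())
        assert np.all(np.diff(clipped.ravel()[ranks]) >= 0)  # order preserved

    def test_quantile_one_limit_is_identity(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        np.testing.assert_allclose(hotspot_clip(img, 1 - 1e-12), img)

    def test_constant_image_unchanged_by_denoise(self):
        img = np.full((9, 9), 2.0)
        for s in ("weak", "strong"):
            np.testing.assert_array_equal(median_denoise(img, s), img)

    def test_spike_removed_by_weak(self):
        img = np.zeros((9, 9))
        img[4, 4] = 10.0
        assert median_denoise(img, "weak")[4, 4] == 0.0

    def test_checkerboard_matches_direct_median_oracle(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 1.0
        got = median_denoise(img, "weak")
        pad = np.pad(img, 1, mode="symmetric")  # scipy 'reflect' edge convention
        expected = np.empty_like(img)
        for i in range(8):
            for j in range(8):
                expected[i, j] = np.median(pad[i : i + 3, j : j + 3])
        np.testing.assert_array_equal(got, expected)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000), q=st.floats(0.5, 0.99))
    def test_filters_stay_within_input_range(self, seed, q):
        img = np.random.default_rng(seed).uniform(-5, 5, (12, 12))
        for out in (hotspot_clip(img, q), median_denoise(img, "weak"), median_denoise(img, "strong")):
            assert out.min() >= img.min() - 1e-12
            assert out.max() <= img.max() + 1e-12


class TestDeisotope:
    def _fl(self, mzs):
        return FeatureList(np.asarray(mzs), np.full(len(mzs), 3.0))

    def test_less_abundant_satellite_removed(self):
        feats = self._fl([500.0, 501.00336])
        out = deisotope(feats, np.array([10.0, 4.0]))
        np.testing.assert_allclose(out.mz, [500.0])

    def test_distant_pair_kept(self):
        feats = self._fl([500.0, 501.5])
        out = deisotope(feats, np.array([10.0, 4.0]))
        assert len(out) == 2

    def test_chain_keeps_only_monoisotopic(self):
        feats = self._fl([500.0, 501.00336, 502.00672])
        out = deisotope(feats, np.array([10.0, 5.0, 2.0]))
        np.testing.assert_allclose(out.mz, [500.0])

    def test_more_abundant_upper_peak_survives(self):
        feats = self._fl([500.0, 501.00336])
        out = deisotope(feats, np.array([4.0, 10.0]))
        assert len(out) == 2

    def test_salt_adduct_removal_flag(self):
        feats = self._fl([500.0, 521.98194, 537.95588])
        out = deisotope(feats, np.array([10.0, 8.0, 6.0]), remove_salt_adducts=True)
        np.testing.assert_allclose(out.mz, [500.0])
        out2 = deisotope(feats, np.array([10.0, 8.0, 6.0]))
        assert len(out2) == 3


class TestBackgroundAndRefine:
    def test_background_removed_within_tolerance(self):
        feats = FeatureList(np.array([314.15260, 500.0]), np.array([3.0]))
        out = remove_background_features(feats, [314.152598], tol_ppm=5.0)
        np.testing.assert_allclose(out.mz, [500.0])

    def test_refine_recenters_apex_and_tightens(self):
        # apex slightly off the true peak center
        mean = _spec([499.999, 500.0, 500.001], [5.0, 10.0, 5.0])
        feats = FeatureList(np.array([500.0005]), np.array([5.0]))
        out = refine_feature_list(feats, mean, 3.0)
        assert out.ppm[0] == 3.0
        assert abs(out.mz[0] - 500.0) < 5e-4

    def test_export_image_round_trips_delimited_grid(self, rng, tmp_path):
        from lipidmsi.preprocess import export_image

        img = rng.uniform(0, 10, (5, 7))
        p = export_image(img, tmp_path / "img.tsv")
        back = np.loadtxt(p, delimiter="\t")
        np.testing.assert_allclose(back, img, rtol=1e-5)
        png = export_image(img, tmp_path / "img.png")
        assert png.exists()

    def test_feature_image_grid_placement(self):
        d = _ds([_spec([500.0], [2.0], 1, 1), _spec([500.0], [4.0], 2, 1)], (1, 2))
        feats = FeatureList(np.array([500.0]), np.array([3.0]))
        img = feature_image(d, feats, 0)
        np.testing.assert_allclose(img, [[2.0, 4.0]])
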