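"""Noise model, candidate segmentation, radial-symmetry localisation and
contrast measurement."""

import math

import numpy as np
import pytest
from scipy import stats

from iscatflow import DetectionConfig, InstrumentConfig, synthgen
from iscatflow.locfind import (LocalizationError, NoiseMap, detect_candidates,
                               dedupe_mosaic, global_noise, local_noise,
                               localize_frame, localize_radial_symmetry,
                               measure_contrast, snr_map)


def gaussian_spot(shape, cx, cy, amplitude, sigma=1.007):
    y, x = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2))


class TestGlobalNoise:
    def test_constant_image_gives_zero(self):
        assert global_noise(np.full((32, 32), 5.0)) == 0.0

    def test_gaussian_noise_recovered_within_two_percent(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0, 2.0, (1024, 1024))
        assert global_noise(img) == pytest.approx(2.0, rel=0.02)

    def test_two_level_image_hand_computed(self):
        # values {-1, +1} equally: median 0, MAD = 1, sigma = 1.4826
        img = np.tile([[-1.0, 1.0]], (16, 16))
        assert global_noise(img) == pytest.approx(1.4826, rel=1e-12)


class TestLocalNoise:
    def test_homogeneous_noise_flat_map(self):
        rng = np.random.default_rng(2)
        img = rng.normal(0, 1.0, (256, 256))
        nm = local_noise(img, global_noise(img))
        assert np.abs(nm.local_sigma - 1.0).max() < 0.10

    def test_bright_spot_excluded_from_noise(self):
        """A 20-sigma spot must not inflate the local noise under it."""
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1.0, (256, 256))
        spot = gaussian_spot((256, 256), 128, 128, 20.0)
        nm_clean = local_noise(noise, 1.0)
        nm_spot = local_noise(noise + spot, 1.0)
        centre_change = abs(nm_spot.local_sigma[128, 128]
                            - nm_clean.local_sigma[128, 128])
        assert centre_change / nm_clean.local_sigma[128, 128] < 0.05

    def test_fallback_to_global_when_all_excluded(self):
        img = np.zeros((128, 128))
        img[::2, ::2] = 100.0  # everything either 0 (inlier) or excluded
        img[1::2, :] = 100.0
        img[:, 1::2] = 100.0
        nm = local_noise(img, 1.0)
        # windows dominated by excluded pixels fall back to the global sigma
        assert nm.local_sigma.max() <= 1.0
        assert nm.local_sigma.min() >= 0.25  # floor

    def test_zero_global_sigma_rejected(self):
        with pytest.raises(ValueError):
            local_noise(np.zeros((32, 32)), 0.0)


class TestSnrMap:
    def test_uniform_ratio(self):
        noise = NoiseMap(local_sigma=np.full((16, 16), 2.0), global_sigma=2.0)
        img = np.full((16, 16), 8.0)
        np.testing.assert_array_equal(snr_map(img, noise), 4.0)

    def test_linear_in_image(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(32, 32))
        noise = NoiseMap(local_sigma=np.full((32, 32), 0.5), global_sigma=0.5)
        np.testing.assert_allclose(snr_map(2 * img, noise),
                                   2 * snr_map(img, noise))

    def test_magnitude_detects_dark_spots(self):
        noise = NoiseMap(local_sigma=np.ones((8, 8)), global_sigma=1.0)
        img = np.full((8, 8), -5.0)
        np.testing.assert_array_equal(snr_map(img, noise), 5.0)


class TestDetectCandidates:
    cfg = DetectionConfig(border_margin_px=0)

    def test_single_hot_pixel_rejected_by_cluster_rule(self):
        snr = np.zeros((64, 64))
        snr[30, 30] = 10.0
        assert detect_candidates(snr, self.cfg) == []

    def test_three_adjacent_pixels_one_candidate(self):
        snr = np.zeros((64, 64))
        snr[30, 30:33] = 5.0
        cands = detect_candidates(snr, self.cfg)
        assert len(cands) == 1
        assert (cands[0].row, cands[0].col) == (30, 30)

    def test_all_subthreshold_gives_nothing(self):
        snr = np.full((64, 64), 3.9)
        assert detect_candidates(snr, self.cfg) == []

    def test_nearby_candidates_merged_keeping_brighter(self):
        snr = np.zeros((64, 64))
        snr[10, 10:13] = 5.0
        snr[12, 10:13] = 8.0  # second cluster 2 px away, brighter
        cands = detect_candidates(snr, self.cfg)
        assert len(cands) == 1
        assert cands[0].peak_snr == 8.0

    def test_border_margin_excludes_edge_detections(self):
        snr = np.zeros((64, 64))
        snr[2, 10:13] = 9.0
        assert detect_candidates(snr, DetectionConfig(border_margin_px=8)) == []


class TestRadialSymmetry:
    def test_pixel_centred_spot_exact(self):
        img = gaussian_spot((21, 21), 10, 10, 1.0)
        x, y = localize_radial_symmetry(img, (10, 10))
        assert math.hypot(x - 10, y - 10) < 1e-6

    def test_subpixel_noiseless_accuracy(self):
        img = gaussian_spot((21, 21), 10.30, 9.80, 1.0)
        x, y = localize_radial_symmetry(img, (10, 10))
        assert math.hypot(x - 10.30, y - 9.80) < 0.05

    def test_against_weighted_centroid_oracle(self):
        img = gaussian_spot((21, 21), 10.25, 10.15, 1.0)
        x, y = localize_radial_symmetry(img, (10, 10))
        # intensity-weighted centroid over the same 9x9 window
        roi = img[6:15, 6:15]
        yy, xx = np.mgrid[6:15, 6:15]
        cx = (roi * xx).sum() / roi.sum()
        cy = (roi * yy).sum() / roi.sum()
        assert math.hypot(x - cx, y - cy) < 0.2

    def test_dark_spot_localised_like_bright(self):
        img = -gaussian_spot((21, 21), 10.30, 9.80, 1.0)
        x, y = localize_radial_symmetry(img, (10, 10))
        assert math.hypot(x - 10.30, y - 9.80) < 0.05

    def test_flat_roi_raises(self):
        with pytest.raises(LocalizationError):
            localize_radial_symmetry(np.ones((21, 21)), (10, 10))


class TestMeasureContrast:
    def test_noiseless_peak_recovered_at_any_subpixel_position(self, small_cfg):
        for (cx, cy) in [(100.0, 100.0), (100.5, 100.5), (100.3, 99.8)]:
            spot = synthgen.GroundTruthSpot(x=cx, y=cy, contrast=0.02)
            frame, _ = synthgen.simulate_frame([spot], small_cfg,
                                               shot_noise=False)
            from iscatflow.imgproc import normalize_frame, remove_large_features
            img = remove_large_features(normalize_frame(frame))
            peak, _ = measure_contrast(img, (cx, cy))
            assert peak == pytest.approx(0.02, rel=0.02)

    def test_integrated_contrast_linear_in_amplitude(self):
        img1 = gaussian_spot((21, 21), 10.2, 10.4, 0.01)
        img2 = gaussian_spot((21, 21), 10.2, 10.4, 0.02)
        _, i1 = measure_contrast(img1, (10.2, 10.4))
        _, i2 = measure_contrast(img2, (10.2, 10.4))
        assert i2 == pytest.approx(2 * i1, rel=1e-9)

    def test_centre_outside_image_rejected(self):
        with pytest.raises(ValueError):
            measure_contrast(np.ones((16, 16)), (100, 2))

    def test_contrast_distribution_recovered(self, small_cfg):
        """Log-normal seeded contrasts of SNR >= 8 spots are recovered with a
        distribution indistinguishable from truth (KS at alpha = 0.01)."""
        mu, sigma_ln = math.log(0.15), 0.25
        rng = np.random.default_rng(7)
        measured, truth_vals = [], []
        for k in range(6):
            spots = synthgen.random_spots(
                40, tuple(small_cfg.frame_shape), rng,
                synthgen.lognormal_contrast(mu, sigma_ln),
                min_separation_px=16, margin_px=12)
            frame, truth = synthgen.simulate_frame(
                spots, small_cfg, shot_noise=True, seed=100 + k)
            from iscatflow.imgproc import normalize_frame, remove_large_features
            img = remove_large_features(normalize_frame(frame))
            tab = localize_frame(img, DetectionConfig())
            measured.extend(tab["peak_contrast"])
            truth_vals.extend(truth["contrast"])
        assert len(measured) > 150
        p = stats.ks_2samp(measured, truth_vals).pvalue
        assert p > 0.01


class TestDedupe:
    def table(self, rows):
        import pandas as pd
        return pd.DataFrame(rows, columns=["x_px", "y_px", "snr",
                                           "peak_contrast"])

    def test_duplicate_across_tiles_merged(self):
        t0 = self.table([[100.0, 50.0, 10.0, 0.02]])
        t1 = self.table([[10.0, 50.0, 9.0, 0.02]])  # same spot, tile at col 90
        out = dedupe_mosaic([t0, t1], [(0, 0), (0, 90)], radius_px=2.0)
        assert len(out) == 1
        assert out["snr"].iloc[0] == 10.0  # higher-SNR record kept

    def test_distinct_spots_kept(self):
        t0 = self.table([[100.0, 50.0, 10.0, 0.02],
                         [110.0, 50.0, 8.0, 0.01]])
        out = dedupe_mosaic([t0], [(0, 0)], radius_px=2.0)
        assert len(out) == 2

    def test_count_conservation(self):
        t0 = self.table([[10.0, 10.0, 5.0, 0.01], [10.5, 10.5, 4.0, 0.01],
                         [40.0, 40.0, 6.0, 0.01]])
        out = dedupe_mosaic([t0], [(0, 0)], radius_px=2.0)
        assert len(out) == 2  # merged + kept = input


class TestDetectionPerformance:
    def test_recall_monotone_in_snr(self, small_cfg):
        """Detection recall rises monotonically with spot SNR and vanishes
        for spots buried in the noise."""
        from conftest import make_sparse_frame

        from iscatflow.imgproc import normalize_frame, remove_large_features
        noise_sigma = 1.0 / math.sqrt(small_cfg.background_counts)
        recalls = []
        for snr_target in (1.0, 4.0, 10.0):
            hits = total = 0
            for k in range(3):
                frame, truth = make_sparse_frame(
                    small_cfg, snr_target * noise_sigma,
                    n_spots=20, seed=10 * int(snr_target) + k)
                img = remove_large_features(normalize_frame(frame))
                tab = localize_frame(img, DetectionConfig())
                from scipy.spatial import cKDTree
                if len(tab):
                    tree = cKDTree(tab[["x_px", "y_px"]].to_numpy())
                    d, _ = tree.query(truth[["x_px", "y_px"]].to_numpy())
                    hits += (d <= 2.0).sum()
                total += len(truth)
            recalls.append(hits / total)
        assert recalls[0] < 0.2
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] > 0.95
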