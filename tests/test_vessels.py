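"""Vessel segmentation, smoothing, variance explained, and outlier fences."""

import numpy as np
import pytest

from hemoccl import (
    RoiMask,
    iqr_outlier_mask,
    moving_average,
    variance_explained,
    vessel_area_trace,
    vessel_lumen_trace,
)

RATE = 15.0


def _disk_video(radius, shape=(512, 512), dark=0.0, bright=100.0, frames=1):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    disk = (yy - shape[0] // 2) ** 2 + (xx - shape[1] // 2) ** 2 <= radius**2
    img = np.full(shape, bright)
    img[disk] = dark
    return np.repeat(img[None], frames, axis=0), disk


class TestVesselAreaTrace:
    def test_dark_disk_area_near_pixel_count(self):
        video, disk = _disk_video(10)
        m = vessel_area_trace(video)
        assert m.area_px2[0] == pytest.approx(disk.sum(), rel=0.05)
        assert m.area_px2[0] == pytest.approx(np.pi * 100, rel=0.05)

    def test_uniform_frame_zero_area(self):
        video = np.full((3, 32, 32), 5.0)
        m = vessel_area_trace(video)
        assert np.all(m.area_px2 == 0.0)

    def test_tracks_true_dilation_sequence(self, rng):
        from hemoccl import SceneConfig, render_frames, simulate_behavior

        cfg = SceneConfig(duration_s=40.0, n_mismatch=0, n_opto=0,
                          grating_interval_s=0, locomotion_prob=0.0, seed=3)
        log = simulate_behavior(cfg)
        t = np.arange(cfg.n_frames) / cfg.frame_rate
        area = cfg.baseline_cross_section_um2 * (1 + 0.25 * np.sin(2 * np.pi * t / 20))
        stack, truth = render_frames(log, area, cfg)
        vy, vx = truth.vessel_center_px
        box = RoiMask.from_rect("vb", "vessel_box", int(vy) - 24, int(vx) - 16,
                                int(vy) + 24, int(vx) + 16)
        m = vessel_area_trace(stack, box)
        assert np.corrcoef(m.area_px2, area)[0, 1] > 0.95

    def test_edge_touching_flagged(self):
        video = np.full((1, 128, 128), 100.0)
        video[0, 0:8, 0:8] = 0.0  # dark blob in the corner
        m = vessel_area_trace(video)
        assert m.ellipses[0].touches_edge

    def test_ellipse_area_within_ten_percent_of_count_for_convex_lumens(self):
        for radius in (4, 7, 12, 20):
            video, disk = _disk_video(radius)
            m = vessel_area_trace(video)
            assert m.area_px2[0] == pytest.approx(disk.sum(), rel=0.10)
        # elongated convex lumen
        yy, xx = np.mgrid[0:384, 0:384]
        ell = ((yy - 192) / 6.0) ** 2 + ((xx - 192) / 18.0) ** 2 <= 1.0
        video = np.full((1, 384, 384), 100.0)
        video[0, ell] = 0.0
        m = vessel_area_trace(video)
        assert m.area_px2[0] == pytest.approx(ell.sum(), rel=0.10)


class TestLumenProxy:
    def test_constriction_raises_proxy_and_anticorrelates_with_area(self):
        from hemoccl import SceneConfig, render_frames, simulate_behavior

        cfg = SceneConfig(duration_s=30.0, n_mismatch=0, n_opto=0,
                          grating_interval_s=0, locomotion_prob=0.0, seed=5)
        log = simulate_behavior(cfg)
        n = cfg.n_frames
        area = cfg.baseline_cross_section_um2 * np.r_[np.ones(n // 2),
                                                      0.85 * np.ones(n - n // 2)]
        stack, truth = render_frames(log, area, cfg)
        vy, vx = truth.vessel_center_px
        lum = RoiMask.from_rect("l", "vessel_lumen", int(vy) - 1, int(vx) - 1,
                                int(vy) + 2, int(vx) + 2)
        proxy = vessel_lumen_trace(stack, lum, RATE)
        assert proxy[-1] > proxy[0]  # constriction brightens the lumen ROI
        assert np.corrcoef(proxy, area)[0, 1] < -0.9

    def test_constant_vessel_flat_proxy(self):
        from hemoccl import SceneConfig, render_frames, simulate_behavior

        cfg = SceneConfig(duration_s=10.0, n_mismatch=0, n_opto=0,
                          grating_interval_s=0, locomotion_prob=0.0, seed=5)
        log = simulate_behavior(cfg)
        area = np.full(cfg.n_frames, cfg.baseline_cross_section_um2)
        stack, truth = render_frames(log, area, cfg)
        vy, vx = truth.vessel_center_px
        lum = RoiMask.from_rect("l", "vessel_lumen", int(vy) - 1, int(vx) - 1,
                                int(vy) + 2, int(vx) + 2)
        proxy = vessel_lumen_trace(stack, lum, RATE)
        assert np.allclose(proxy, 0.0)


class TestMovingAverage:
    def test_constant_unchanged(self):
        x = np.full(50, 4.2)
        assert np.allclose(moving_average(x, RATE, 0.5), 4.2)

    def test_impulse_spread(self):
        x = np.zeros(31)
        x[15] = 1.0
        sm = moving_average(x, frame_rate=6.0, width_s=0.5)  # 3-frame boxcar
        assert sm[14] == pytest.approx(1 / 3)
        assert sm[15] == pytest.approx(1 / 3)
        assert sm[16] == pytest.approx(1 / 3)
        assert sm[13] == 0.0

    def test_mean_preserved_away_from_edges(self, rng):
        x = rng.normal(size=500)
        sm = moving_average(x, RATE, 0.5)
        assert sm[50:-50].mean() == pytest.approx(
            moving_average(x, RATE, 0.5)[50:-50].mean())
        assert abs(sm.mean() - x.mean()) < 0.01


class TestVarianceExplained:
    def test_affine_relation_is_one(self, rng):
        x = rng.normal(size=300)
        assert variance_explained(x, 2 * x + 3) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert variance_explained(x, y) < 0.02

    def test_one_to_one_noise_ratio(self, rng):
        x = rng.normal(size=20000)
        y = x + rng.normal(size=20000)
        assert variance_explained(x, y) == pytest.approx(0.5, abs=0.1)

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.normal(size=400)
        y = 0.3 * x + rng.normal(0, 0.5, 400)
        r2 = variance_explained(x, y)
        assert variance_explained(y, x) == pytest.approx(r2)
        assert variance_explained(5 * x - 2, y) == pytest.approx(r2)
        assert variance_explained(x, -3 * y + 1) == pytest.approx(r2)

    def test_windowed_mode(self, rng):
        rate = 15.0
        n = 300
        x = rng.normal(size=n)
        y = x.copy()
        y[:100] = rng.normal(size=100)  # uncorrelated before the window
        onset = 150
        r2 = variance_explained(x, y, frame_rate=rate, window_s=(-2.0, 6.0),
                                onset_frame=onset)
        assert r2 == pytest.approx(1.0)

    def test_zero_variance_is_nan(self):
        assert np.isnan(variance_explained(np.ones(50), np.arange(50.0)))


class TestIqrOutliers:
    def test_single_outlier(self):
        mask = iqr_outlier_mask(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert list(mask) == [False, False, False, False, True]

    def test_uniform_none_masked(self):
        assert not iqr_outlier_mask(np.full(10, 3.0)).any()

    def test_symmetric_fences(self):
        v = np.array([-5.0, -1.0, 0.0, 1.0, 5.0, -50.0, 50.0])
        mask = iqr_outlier_mask(v)
        assert mask[v == 50.0][0] == mask[v == -50.0][0] == True

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            iqr_outlier_mask(np.array([1.0, 2.0, 3.0]))
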