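"""Forward-model contracts: behaviour schedules, vessel kernels, occlusion."""

import math

import numpy as np
import pytest

from hemoccl import (
    SceneConfig,
    compute_occlusion_footprint,
    effective_frame_rate,
    occlusion_attenuation,
    render_frames,
    simulate_behavior,
    simulate_vessel_dynamics,
)
from hemoccl.config import CouplingKernel
from hemoccl.synthetic import SchedulingError


def _quiet_config(**kw):
    base = dict(duration_s=80.0, n_mismatch=0, n_opto=0, grating_interval_s=0,
                locomotion_prob=0.0, seed=0)
    base.update(kw)
    return SceneConfig(**base)


class TestSimulateBehavior:
    def test_no_locomotion_means_no_mismatch(self):
        log = simulate_behavior(_quiet_config(n_mismatch=5, duration_s=120.0))
        assert np.all(log.running_speed_cmps == 0)
        assert not log.mismatch_on.any()

    def test_mismatch_windows_satisfy_locomotion_rule(self):
        cfg = SceneConfig(duration_s=240.0, n_mismatch=6, seed=3)
        log = simulate_behavior(cfg)
        onsets = np.flatnonzero(log.mismatch_on & ~np.r_[False, log.mismatch_on[:-1]])
        assert len(onsets) > 0
        pre = int(round(0.5 * cfg.frame_rate))
        post = int(round(1.0 * cfg.frame_rate))
        for f in onsets:
            window = log.running_speed_cmps[f - pre:f + post]
            assert np.all(window >= 0.25)

    def test_same_seed_identical_logs(self):
        cfg = SceneConfig(duration_s=90.0, n_mismatch=3, seed=7)
        a = simulate_behavior(cfg)
        b = simulate_behavior(cfg)
        assert np.array_equal(a.running_speed_cmps, b.running_speed_cmps)
        assert np.array_equal(a.mismatch_on, b.mismatch_on)
        assert np.array_equal(a.grating_on, b.grating_on)

    def test_contexts(self):
        closed = simulate_behavior(SceneConfig(duration_s=120.0, seed=2))
        mm = closed.mismatch_on
        assert np.all(closed.visual_flow_cmps[~mm] == closed.running_speed_cmps[~mm])
        assert np.all(closed.visual_flow_cmps[mm] == 0)
        dark = simulate_behavior(SceneConfig(duration_s=120.0, context="dark",
                                             n_mismatch=0, seed=2))
        assert np.all(dark.visual_flow_cmps == 0)
        open_ = simulate_behavior(SceneConfig(duration_s=120.0, context="open_loop",
                                              n_mismatch=0, seed=2))
        assert not np.array_equal(open_.visual_flow_cmps, open_.running_speed_cmps)

    def test_too_short_session_raises(self):
        with pytest.raises(SchedulingError):
            simulate_behavior(SceneConfig(duration_s=0.5, n_mismatch=2, seed=0,
                                          grating_interval_s=0))


class TestVesselDynamics:
    def test_zero_kernels_zero_noise_constant(self):
        cfg = _quiet_config()
        cfg.coupling_kernels = {k: CouplingKernel(0.0) for k in cfg.coupling_kernels}
        log = simulate_behavior(cfg)
        area = simulate_vessel_dynamics(log, cfg)
        assert np.allclose(area, cfg.baseline_cross_section_um2)

    def test_single_event_peak_matches_amplitude(self):
        cfg = _quiet_config(grating_interval_s=60.0, duration_s=70.0)
        cfg.coupling_kernels = {
            "locomotion_onset": CouplingKernel(0.0),
            "grating_onset": CouplingKernel(0.1),
            "mismatch": CouplingKernel(0.0),
            "opto": CouplingKernel(0.0),
        }
        log = simulate_behavior(cfg)
        assert log.grating_on.any()
        area = simulate_vessel_dynamics(log, cfg)
        # kernel is normalized so its discretized maximum is the amplitude
        assert area.max() == pytest.approx(1.1 * cfg.baseline_cross_section_um2,
                                           rel=1e-9)

    def test_constriction_dips_below_baseline_after_locomotion_onset(self):
        from hemoccl.synthetic import BehaviorLog

        cfg = _quiet_config(duration_s=60.0)
        cfg.coupling_kernels = {k: CouplingKernel(0.0) for k in cfg.coupling_kernels}
        cfg.coupling_kernels["locomotion_onset"] = CouplingKernel(-0.1)
        n = cfg.n_frames
        speed = np.zeros(n)
        speed[n // 2:] = 5.0  # one clean locomotion onset at n//2
        z = np.zeros(n, bool)
        log = BehaviorLog(time_s=np.arange(n) / 15.0, running_speed_cmps=speed,
                          visual_flow_cmps=speed.copy(), grating_on=z,
                          mismatch_on=z, opto_on=z, frame_rate=15.0)
        area = simulate_vessel_dynamics(log, cfg)
        assert np.all(area[:n // 2] == cfg.baseline_cross_section_um2)
        assert area.min() < cfg.baseline_cross_section_um2
        assert area.min() >= (1 - 0.1 - 1e-9) * cfg.baseline_cross_section_um2


class TestOcclusionAttenuation:
    def test_identity_at_baseline(self):
        assert occlusion_attenuation(400.0, 400.0, 0.7) == pytest.approx(1.0)

    def test_stated_formula(self):
        # k = 0.5 and a 10% dilation give a 5% attenuation
        assert occlusion_attenuation(440.0, 400.0, 0.5) == pytest.approx(0.95)

    def test_zero_gain(self):
        assert occlusion_attenuation(1234.0, 400.0, 0.0) == pytest.approx(1.0)

    def test_clamped(self):
        assert occlusion_attenuation(400.0 * 100, 400.0, 1.0) == pytest.approx(0.05)

    def test_sign_convention(self):
        # dilation darkens, constriction brightens
        assert occlusion_attenuation(440.0, 400.0, 0.5) < 1.0
        assert occlusion_attenuation(360.0, 400.0, 0.5) > 1.0


class TestFootprint:
    def test_worked_example_500um_45deg(self):
        assert compute_occlusion_footprint(500.0, 45.0) == pytest.approx(1000.0)

    def test_zero_depth(self):
        assert compute_occlusion_footprint(0.0, 45.0) == 0.0

    def test_closed_form_scaling(self):
        assert compute_occlusion_footprint(250.0, 45.0) == pytest.approx(500.0)

    def test_matches_independent_trigonometry(self, rng):
        for _ in range(20):
            depth = rng.uniform(0, 800)
            angle = rng.uniform(0, 89)
            rad = math.radians(angle)
            expected = 2.0 * depth * math.sin(rad) / math.cos(rad)
            got = compute_occlusion_footprint(depth, angle)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_invalid_angle(self):
        with pytest.raises(ValueError):
            compute_occlusion_footprint(100.0, 90.0)


class TestEffectiveFrameRate:
    def test_four_plane_resonant_scan(self):
        assert effective_frame_rate(60.0, 4) == pytest.approx(15.0)

    def test_single_plane(self):
        assert effective_frame_rate(30.0, 1) == pytest.approx(30.0)

    def test_invalid_planes(self):
        with pytest.raises(ValueError):
            effective_frame_rate(60.0, 0)


class TestRenderFrames:
    def test_static_scene_all_frames_identical(self):
        cfg = _quiet_config(duration_s=5.0)
        log = simulate_behavior(cfg)
        area = np.full(cfg.n_frames, cfg.baseline_cross_section_um2)
        stack, _ = render_frames(log, area, cfg)
        assert np.array_equal(stack[0], stack[1])
        assert np.array_equal(stack[0], stack[-1])

    def test_injected_shift_is_exact_translation(self, jitter_scene):
        truth = jitter_scene.truth
        stack = jitter_scene.stack
        cfg = jitter_scene.config
        area = jitter_scene.cross_section_um2
        # re-render without jitter to get the unshifted frames
        cfg0 = SceneConfig(**{**cfg.to_dict(), "jitter_amplitude_px": 0})
        stack0, _ = render_frames(jitter_scene.behavior, area, cfg0)
        t = int(np.flatnonzero(np.abs(truth.injected_shifts).sum(axis=1))[0])
        dy, dx = truth.injected_shifts[t]
        h, w = stack.shape[1:]
        ys = slice(max(dy, 0), min(h + dy, h))
        xs = slice(max(dx, 0), min(w + dx, w))
        ys0 = slice(max(-dy, 0), min(h - dy, h))
        xs0 = slice(max(-dx, 0), min(w - dx, w))
        assert np.allclose(stack[t][ys, xs], stack0[t][ys0, xs0])

    def test_lumen_intensity_inverse_in_area(self):
        cfg = _quiet_config(duration_s=20.0)
        log = simulate_behavior(cfg)
        t = np.arange(cfg.n_frames) / cfg.frame_rate
        area = cfg.baseline_cross_section_um2 * (1 + 0.2 * np.sin(2 * np.pi * t / 10))
        stack, truth = render_frames(log, area, cfg)
        vy, vx = truth.vessel_center_px
        lumen = stack[:, int(vy) - 1:int(vy) + 2, int(vx) - 1:int(vx) + 2].mean(axis=(1, 2))
        assert np.corrcoef(lumen, area)[0, 1] < -0.95

    def test_occlusion_sign_on_rendered_soma(self):
        # constriction (negative kernel) must brighten the rendered soma
        cfg = _quiet_config(duration_s=20.0)
        log = simulate_behavior(cfg)
        n = cfg.n_frames
        dip = cfg.baseline_cross_section_um2 * np.r_[np.ones(n // 2),
                                                     0.9 * np.ones(n - n // 2)]
        stack, truth = render_frames(log, dip, cfg)
        cy, cx = truth.soma_centers_px[0]
        soma = stack[:, int(cy), int(cx)]
        assert soma[-1] > soma[0]

    def test_determinism(self):
        cfg = SceneConfig(duration_s=10.0, n_mismatch=0, n_opto=0, seed=11,
                          photon_scale=2.0, jitter_amplitude_px=2)
        log = simulate_behavior(cfg)
        area = simulate_vessel_dynamics(log, cfg)
        s1, _ = render_frames(log, area, cfg)
        s2, _ = render_frames(log, area, cfg)
        assert np.array_equal(s1, s2)

    def test_vessel_out_of_bounds_rejected(self):
        cfg = _quiet_config(duration_s=5.0, vessel_center_um=(4.0, 64.0))
        log = simulate_behavior(cfg)
        area = np.full(cfg.n_frames, cfg.baseline_cross_section_um2)
        with pytest.raises(ValueError):
            render_frames(log, area, cfg)
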