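"""End-to-end orchestration: simulate, preprocess, analyse, report.

A single seed fans out deterministically to per-stage child seeds, so a
full run is reproducible and each stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io
from .bootstrap import NestedSamples, bootstrap_se_band, hierarchical_bootstrap_mean
from .config import RunConfig, SceneConfig
from .correlations import pairwise_state_correlations, state_correlation_table
from .events import detect_all_events, locomotion_state_mask
from .preprocess import RoiMask, dff_pipeline
from .responses import (
    baseline_subtract,
    event_triggered_matrix,
    responsive_fraction,
    test_responsive,
    trial_mean_response,
)
from .synthetic import SceneData, simulate_scene
from .vessels import moving_average, variance_explained, vessel_area_trace, vessel_lumen_trace

logger = logging.getLogger(__name__)

__all__ = ["stage_seeds", "scene_rois", "run_pipeline", "make_fixtures"]


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic child seeds (< 2**31) fanned out from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def scene_rois(scene: SceneData) -> list[RoiMask]:
    """Square soma ROIs from ground-truth geometry plus vessel ROIs."""
    cfg = scene.config
    h, w = cfg.frame_shape
    rois = []
    # inscribed square, fully inside the soma disk, so the trace is not
    # diluted by unmodulated neuropil at the ROI corners
    r = max(1, int(np.floor(scene.truth.soma_radius_px / np.sqrt(2.0))))
    for i, (cy, cx) in enumerate(scene.truth.soma_centers_px):
        y0 = max(0, int(round(cy)) - r)
        x0 = max(0, int(round(cx)) - r)
        y1 = min(h, int(round(cy)) + r + 1)
        x1 = min(w, int(round(cx)) + r + 1)
        rois.append(RoiMask.from_rect(f"soma{i}", "soma", y0, x0, y1, x1))
    vy, vx = scene.truth.vessel_center_px
    a0_px2 = cfg.baseline_cross_section_um2 / cfg.pixel_size_um**2
    b = np.sqrt(a0_px2 / (np.pi * cfg.vessel_axis_ratio))  # resting semi-minor
    a = b * cfg.vessel_axis_ratio
    half = int(np.ceil(max(a, b))) + 10  # generous neuropil margin around the vessel
    rois.append(RoiMask.from_rect(
        "vessel_box", "vessel_box",
        max(0, int(vy) - half), max(0, int(vx) - half),
        min(h, int(vy) + half), min(w, int(vx) + half)))
    lum = max(1, int(b * 0.4))
    rois.append(RoiMask.from_rect(
        "vessel_lumen", "vessel_lumen",
        int(vy) - lum, int(vx) - lum, int(vy) + lum, int(vx) + lum))
    return rois


def run_pipeline(scene_config: SceneConfig, run_config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Simulate a session and run every analysis stage over it.

    Returns a machine-readable summary dictionary; if ``out_dir`` is
    given, also writes the rendered stack, behaviour log, ground truth,
    per-stage CSVs, and the summary JSON there.
    """
    rc = run_config or RunConfig()
    seeds = stage_seeds(rc.seed)
    scene = simulate_scene(scene_config)
    rois = scene_rois(scene)
    soma_rois = [r for r in rois if r.kind == "soma"]

    from .preprocess import register_frames

    registered, shifts = register_frames(scene.stack, radius=rc.registration_radius_px)
    traces, _ = dff_pipeline(
        registered, soma_rois, scene_config.frame_rate,
        window_s=rc.baseline_window_s, percentile=rc.baseline_percentile,
        register=False)

    events = detect_all_events(
        scene.behavior, threshold=rc.speed_threshold_cmps,
        mismatch_threshold=rc.mismatch_threshold_cmps,
        min_above_s=rc.min_above_s, min_below_s=rc.min_below_s,
        mismatch_window_s=rc.mismatch_window_s)

    # --- per-ROI responsiveness and the population onset curve ------------
    responsiveness: dict[str, dict] = {}
    population_curves: dict[str, dict] = {}
    for kind in ("locomotion_onset", "grating_onset", "mismatch", "opto"):
        onsets = events.frames(kind)
        results = []
        neuron_curves = []
        time_axis = None
        for roi in soma_rois:
            m = event_triggered_matrix(traces[roi.roi_id], onsets, kind,
                                       rc.pre_s, rc.post_s)
            if not m.included:
                continue
            m = baseline_subtract(m, profile=rc.response_profile)
            scalars = trial_mean_response(m, profile=rc.response_profile)
            results.append(test_responsive(scalars, rc.alpha, roi.roi_id, kind))
            neuron_curves.append(m.data.mean(axis=0))
            time_axis = m.time_s
        if not results:
            continue
        responsiveness[kind] = {
            "n_tested": len(results),
            "n_responsive": int(sum(r.responsive for r in results)),
            "fraction_responsive": float(np.mean([r.responsive for r in results])),
            "p_values": [r.p_value for r in results],
        }
        nested = NestedSamples(sites=[np.array(neuron_curves)], site_ids=["site0"])
        dist = hierarchical_bootstrap_mean(nested, rc.n_boot_curve, seeds[1])
        band = bootstrap_se_band(dist)
        population_curves[kind] = {
            "time_s": time_axis.tolist(),
            "mean": np.asarray(band.mean).tolist(),
            "lo": np.asarray(band.lo).tolist(),
            "hi": np.asarray(band.hi).tolist(),
        }

    # --- vessel coupling: R^2 per event kind ------------------------------
    vessel_box = next(r for r in rois if r.kind == "vessel_box")
    lumen_roi = next(r for r in rois if r.kind == "vessel_lumen")
    lumen = vessel_lumen_trace(registered, lumen_roi, scene_config.frame_rate,
                               rc.baseline_window_s, rc.baseline_percentile)
    neuronal_mean = np.mean([traces[r.roi_id].values for r in soma_rois], axis=0)
    rate = scene_config.frame_rate
    pre_f = int(round(-rc.r2_window_s[0] * rate))
    post_f = int(round(rc.r2_window_s[1] * rate))
    r2_table = []
    for kind in ("locomotion_onset", "grating_onset", "mismatch", "opto"):
        onsets = [f for f in events.frames(kind)
                  if f - pre_f >= 0 and f + post_f <= len(scene.behavior)]
        if len(onsets) < 1:
            continue
        avg_video = np.mean([registered[f - pre_f:f + post_f] for f in onsets], axis=0)
        area = vessel_area_trace(avg_video, vessel_box, rc.vessel_percentile).area_px2
        lum_avg = np.mean([lumen[f - pre_f:f + post_f] for f in onsets], axis=0)
        neu_avg = np.mean([neuronal_mean[f - pre_f:f + post_f] for f in onsets], axis=0)
        sm = lambda x: moving_average(x, rate, rc.smooth_width_s)
        r2_table.append({
            "event": kind,
            "n_events": len(onsets),
            "r2_area_vs_neurons": variance_explained(sm(area), sm(neu_avg)),
            "r2_lumen_vs_neurons": variance_explained(sm(lum_avg), sm(neu_avg)),
        })
    r2_full = variance_explained(
        moving_average(lumen, rate, rc.smooth_width_s),
        moving_average(neuronal_mean, rate, rc.smooth_width_s))

    # --- state-dependent pairwise correlations ----------------------------
    state = locomotion_state_mask(scene.behavior.running_speed_cmps,
                                  rc.speed_threshold_cmps)
    corr = pairwise_state_correlations(
        {r.roi_id: traces[r.roi_id].values for r in soma_rois}, state,
        rc.state_min_frames)

    summary = {
        "config": {"scene": scene.config.to_dict(), "run": rc.to_dict()},
        "n_frames": len(scene.behavior),
        "events": {k: len(events.frames(k)) for k in
                   ("locomotion_onset", "grating_onset", "mismatch", "opto")},
        "responsiveness": responsiveness,
        "population_curves": population_curves,
        "r2_per_event": r2_table,
        "r2_entire_recording_lumen_vs_neurons": r2_full,
        "state_correlations": [vars(c) for c in corr],
        "registration_max_shift": int(np.abs(shifts).max()),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_stack(scene.stack, out / "stack.tif")
        io.write_behavior(scene.behavior, out / "behavior.csv")
        io.write_truth(scene.truth, out / "truth.csv")
        io.write_rois(rois, out / "rois.csv")
        io.write_traces(traces, out / "traces.csv", shifts)
        io.write_events(events, out / "events.csv")
        (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
        (out / "report.txt").write_text(_report_text(summary))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _report_text(summary: dict) -> str:
    lines = ["hemodynamic occlusion pipeline report", "=" * 38, ""]
    lines.append(f"frames analysed: {summary['n_frames']}")
    lines.append("events: " + ", ".join(f"{k}={v}" for k, v in summary["events"].items()))
    lines.append("")
    for kind, r in summary["responsiveness"].items():
        lines.append(f"{kind}: {r['n_responsive']}/{r['n_tested']} ROIs responsive "
                     f"(fraction {r['fraction_responsive']:.2f})")
    lines.append("")
    for row in summary["r2_per_event"]:
        lines.append(f"R^2 ({row['event']}, {row['n_events']} events): "
                     f"area vs neurons {row['r2_area_vs_neurons']:.2f}, "
                     f"lumen vs neurons {row['r2_lumen_vs_neurons']:.2f}")
    r2 = summary["r2_entire_recording_lumen_vs_neurons"]
    lines.append(f"R^2 (entire recording, lumen vs neurons): {r2:.2f}")
    if summary["state_correlations"]:
        loc = np.nanmean([c["corr_locomoting"] for c in summary["state_correlations"]])
        sta = np.nanmean([c["corr_stationary"] for c in summary["state_correlations"]])
        lines.append(f"mean pairwise correlation: locomoting {loc:.3f}, stationary {sta:.3f}")
    return "\n".join(lines) + "\n"


def make_fixtures(seed: int = 0, out_dir: str | Path | None = None,
                  noise: bool = False) -> SceneData:
    """A small standard test scene: 64x64 px, 2 min, 8 somata, one vessel,
    every event type, with ground truth attached."""
    cfg = SceneConfig(
        duration_s=120.0,
        n_mismatch=4,
        n_opto=3,
        mean_bout_s=12.0,
        mean_rest_s=10.0,
        photon_scale=2.0 if noise else 0.0,
        seed=seed,
    )
    scene = simulate_scene(cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_stack(scene.stack, out / "stack.tif")
        io.write_behavior(scene.behavior, out / "behavior.csv")
        io.write_truth(scene.truth, out / "truth.csv")
        io.write_rois(scene_rois(scene), out / "rois.csv")
    return scene
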