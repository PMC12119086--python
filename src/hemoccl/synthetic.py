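"""Synthetic two-photon scene generator.

Builds a full forward model of a hemodynamic-occlusion imaging session:
a locomoting animal in a virtual corridor (closed-loop, open-loop, or
dark), stimulus schedules (gratings, 1 s visuomotor mismatches, opto
pulses), a surface-vessel cross-section A(t) driven by signed coupling
kernels, multiplicative occlusion of soma fluorescence, and rendered
frame stacks with a Gaussian point-spread proxy, Poisson shot noise, and
optional rigid jitter.  Ground truth for every injected quantity is kept
alongside the rendered stack so downstream stages can be validated
against it.

The occlusion model is first order: a vessel dilated by a fraction
``x = (A - A0)/A0`` attenuates measured fluorescence by ``1 - k*x``
(clamped), so dilation darkens and constriction brightens the apparent
signal — the signature the analysis stages are built to detect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SceneConfig

logger = logging.getLogger(__name__)

__all__ = [
    "BehaviorLog",
    "GroundTruth",
    "SceneData",
    "SchedulingError",
    "simulate_behavior",
    "simulate_vessel_dynamics",
    "occlusion_attenuation",
    "compute_occlusion_footprint",
    "effective_frame_rate",
    "render_frames",
    "simulate_scene",
]

ATTENUATION_CLAMP = 0.05  # lower clamp of the attenuation factor


class SchedulingError(ValueError):
    """Raised when a requested event cannot be placed in the session."""


@dataclass
class BehaviorLog:
    """Per-frame behaviour and stimulus record, synchronized to imaging."""

    time_s: np.ndarray
    running_speed_cmps: np.ndarray
    visual_flow_cmps: np.ndarray
    grating_on: np.ndarray
    mismatch_on: np.ndarray
    opto_on: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("running_speed_cmps", "visual_flow_cmps", "grating_on",
                     "mismatch_on", "opto_on"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time axis")
        if np.any(self.running_speed_cmps < 0) or np.any(self.visual_flow_cmps < 0):
            raise ValueError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "running_speed_cmps": self.running_speed_cmps,
                "visual_flow_cmps": self.visual_flow_cmps,
                "grating_on": self.grating_on.astype(int),
                "mismatch_on": self.mismatch_on.astype(int),
                "opto_on": self.opto_on.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float | None = None) -> "BehaviorLog":
        t = df["time_s"].to_numpy(float)
        if frame_rate is None:
            frame_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 15.0
        return cls(
            time_s=t,
            running_speed_cmps=df["running_speed_cmps"].to_numpy(float),
            visual_flow_cmps=df["visual_flow_cmps"].to_numpy(float),
            grating_on=df["grating_on"].to_numpy(bool),
            mismatch_on=df["mismatch_on"].to_numpy(bool),
            opto_on=df["opto_on"].to_numpy(bool),
            frame_rate=float(frame_rate),
        )


@dataclass
class GroundTruth:
    """Everything injected into the rendered scene, stored losslessly."""

    cross_section_um2: np.ndarray  # (T,)
    attenuation: np.ndarray  # (n_somata, T), in (0, 1] for dilations
    soma_fluorescence: np.ndarray  # (n_somata, T) photons/pixel, pre-occlusion
    injected_shifts: np.ndarray  # (T, 2) integer (dy, dx)
    soma_centers_px: np.ndarray = field(default=None)  # (n_somata, 2) (row, col)
    soma_radius_px: float = 0.0
    vessel_center_px: tuple[float, float] = (0.0, 0.0)
    vessel_axis_ratio: float = 1.0
    vessel_orientation_deg: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        n_somata, T = self.soma_fluorescence.shape
        cols = {"true_cross_section_um2": self.cross_section_um2,
                "true_dy": self.injected_shifts[:, 0],
                "true_dx": self.injected_shifts[:, 1]}
        for i in range(n_somata):
            cols[f"true_fluor_{i}"] = self.soma_fluorescence[i]
            cols[f"true_atten_{i}"] = self.attenuation[i]
        return pd.DataFrame(cols)


@dataclass
class SceneData:
    """Convenience bundle returned by :func:`simulate_scene`."""

    config: SceneConfig
    behavior: BehaviorLog
    cross_section_um2: np.ndarray
    stack: np.ndarray  # (T, H, W) float32
    truth: GroundTruth


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_behavior(config: SceneConfig) -> BehaviorLog:
    """Generate a behaviour log with locomotion bouts and stimulus events.

    Running speed follows a two-state (stationary/locomoting) semi-Markov
    process with exponential dwell times and 0.5 s speed ramps.  Grating
    events recur at the configured interval with gray gaps; 1 s mismatch
    events are injected only where the animal runs above 0.25 cm/s over
    the whole -0.5 to +1 s validity window, so every generated mismatch is
    valid by construction.  Visual flow equals running speed in closed
    loop (except during mismatch halts), is a time-shifted replay in open
    loop, and is zero in dark.
    """
    rng = _child_rngs(config.seed, 4)[0]
    rate = config.frame_rate
    n = config.n_frames
    if config.duration_s < 60.0 and (config.n_mismatch > 0 or config.grating_interval_s > 0):
        logger.warning("duration < 60 s: stimulus schedules may be sparse")

    # --- locomotion: alternating exponential dwells -----------------------
    speed = np.zeros(n)
    if config.locomotion_prob > 0:
        f = 0
        locomoting = rng.random() < config.locomotion_prob
        while f < n:
            if locomoting:
                dwell = max(rng.exponential(config.mean_bout_s), 2.0)
                end = min(n, f + int(round(dwell * rate)))
                target = max(1.0, rng.normal(config.mean_speed_cmps,
                                             0.25 * config.mean_speed_cmps))
                ramp = max(1, int(round(config.speed_ramp_s * rate)))
                seg = np.full(end - f, target)
                seg[:ramp] = np.linspace(0, target, min(ramp, len(seg)), endpoint=False)
                if end < n and len(seg) > ramp:
                    seg[-ramp:] = np.linspace(target, 0, ramp, endpoint=False)
                speed[f:end] = seg
                f = end
                locomoting = False
            else:
                dwell = max(rng.exponential(config.mean_rest_s), 1.5)
                f += int(round(dwell * rate))
                locomoting = rng.random() < config.locomotion_prob or config.locomotion_prob >= 1.0
        # smooth ramps into continuous speed, then add small jitter on top
        speed = ndimage.gaussian_filter1d(speed, sigma=0.2 * rate)
        jitter = rng.normal(0, 0.05 * config.mean_speed_cmps, n)
        speed = np.clip(speed + np.where(speed > 0.5, jitter, 0.0), 0, None)

    # --- gratings ---------------------------------------------------------
    grating = np.zeros(n, dtype=bool)
    if config.grating_interval_s > 0 and config.context != "dark":
        if config.duration_s < config.grating_duration_s:
            raise SchedulingError("session too short to place a grating event")
        dur_f = int(round(config.grating_duration_s * rate))
        f = int(round(config.grating_interval_s * rate * rng.uniform(0.3, 0.8)))
        while f + dur_f <= n:
            grating[f:f + dur_f] = True
            gap = config.grating_interval_s * rng.uniform(0.8, 1.2)
            f += dur_f + int(round(gap * rate))

    # --- opto pulses ------------------------------------------------------
    opto = np.zeros(n, dtype=bool)
    if config.n_opto > 0:
        if config.duration_s < config.opto_duration_s * config.n_opto:
            raise SchedulingError("session too short to place requested opto events")
        dur_f = int(round(config.opto_duration_s * rate))
        starts = np.sort(rng.choice(np.arange(0, n - dur_f, 4 * dur_f),
                                    size=min(config.n_opto, max(1, (n - dur_f) // (4 * dur_f))),
                                    replace=False))
        for s in starts:
            opto[s:s + dur_f] = True

    # --- mismatch: only while running, validity window forced -------------
    mismatch = np.zeros(n, dtype=bool)
    thr = 0.25
    if config.n_mismatch > 0 and config.context == "closed_loop":
        win_pre = int(round(0.5 * rate))
        win_post = int(round(1.0 * rate))
        if n < win_pre + win_post + 1:
            raise SchedulingError("session too short to place a mismatch event")
        above = speed >= thr
        ok = np.array([
            above[f - win_pre:f + win_post].all()
            for f in range(win_pre, n - win_post)
        ])
        eligible = np.flatnonzero(ok) + win_pre
        gap_f = int(round(config.mismatch_min_gap_s * rate))
        chosen: list[int] = []
        pool = list(rng.permutation(eligible))
        for f in pool:
            if len(chosen) >= config.n_mismatch:
                break
            if all(abs(f - c) >= gap_f for c in chosen):
                chosen.append(int(f))
        dur_f = int(round(config.mismatch_duration_s * rate))
        for f in sorted(chosen):
            mismatch[f:f + dur_f] = True
        if len(chosen) < config.n_mismatch:
            logger.warning("placed %d of %d requested mismatch events",
                           len(chosen), config.n_mismatch)

    # --- visual flow ------------------------------------------------------
    if config.context == "closed_loop":
        flow = speed.copy()
        flow[mismatch] = 0.0
    elif config.context == "open_loop":
        flow = np.roll(speed, n // 2)  # replayed, independent of current running
    else:
        flow = np.zeros(n)

    return BehaviorLog(
        time_s=np.arange(n) / rate,
        running_speed_cmps=speed,
        visual_flow_cmps=flow,
        grating_on=grating,
        mismatch_on=mismatch,
        opto_on=opto,
        frame_rate=rate,
    )


def _rising_edges(flags: np.ndarray) -> np.ndarray:
    f = np.asarray(flags, bool)
    return np.flatnonzero(f & ~np.r_[False, f[:-1]])


def _locomotion_onsets_simple(speed: np.ndarray, rate: float, thr: float = 0.25) -> np.ndarray:
    """Onsets by the canonical threshold rule (1 s below, then >= 1 s above)."""
    from .events import detect_onsets

    return detect_onsets(speed, rate, threshold=thr)


def simulate_vessel_dynamics(log: BehaviorLog, config: SceneConfig) -> np.ndarray:
    """Vessel cross-section series A(t) driven by event-coupled kernels.

    ``A(t) = A0 * (1 + sum_events kernel * impulses + noise)``, floored at
    a configurable fraction of A0.  Positive kernel amplitudes dilate the
    vessel (as V1 vessels do on light stimulation); negative amplitudes
    constrict it (as on locomotion onset in ACC).
    """
    n = len(log)
    rate = log.frame_rate
    onsets = {
        "locomotion_onset": _locomotion_onsets_simple(log.running_speed_cmps, rate),
        "grating_onset": _rising_edges(log.grating_on),
        "mismatch": _rising_edges(log.mismatch_on),
        "opto": _rising_edges(log.opto_on),
    }
    drive = np.zeros(n)
    for kind, frames in onsets.items():
        if len(frames) == 0:
            continue
        kernel = config.coupling_kernels.get(kind)
        if kernel is None:
            raise ValueError(f"no coupling kernel configured for event type {kind!r}")
        impulses = np.zeros(n)
        impulses[frames] = 1.0
        k = kernel.sample(rate)
        drive += np.convolve(impulses, k)[:n]
    if config.vessel_noise_sd > 0:
        rng = _child_rngs(config.seed, 4)[1]
        drive = drive + ndimage.gaussian_filter1d(
            rng.normal(0, config.vessel_noise_sd, n), sigma=0.2 * rate)
    area = config.baseline_cross_section_um2 * (1.0 + drive)
    floor = config.vessel_area_floor_frac * config.baseline_cross_section_um2
    n_floored = int(np.sum(area < floor))
    if n_floored:
        logger.warning("vessel area floored at %d frames", n_floored)
    return np.maximum(area, floor)


def occlusion_attenuation(area: np.ndarray | float, a0: float, gain: float) -> np.ndarray | float:
    """Multiplicative attenuation of soma fluorescence by vessel occlusion.

    First-order model: ``factor = 1 - k * (A - A0)/A0`` clamped to
    ``[0.05, 20]``.  Dilation (A > A0) reduces the measured fluorescence,
    constriction increases it.
    """
    if a0 <= 0:
        raise ValueError("A0 must be positive")
    if gain < 0:
        raise ValueError("gain k must be >= 0")
    rel = (np.asarray(area, float) - a0) / a0
    factor = np.clip(1.0 - gain * rel, ATTENUATION_CLAMP, 1.0 / ATTENUATION_CLAMP)
    if np.isscalar(area):
        return float(factor)
    return factor


def compute_occlusion_footprint(depth_um: float, half_angle_deg: float = 45.0) -> float:
    """Diameter (um) of the surface circle through which collected light passes.

    With collection half-angle theta, a neuron at depth d is occludable by
    any surface vessel within a circle of diameter ``2 * d * tan(theta)``:
    500 um depth at 45 degrees gives a 1 mm footprint.
    """
    if depth_um < 0:
        raise ValueError("depth must be >= 0")
    if not 0 <= half_angle_deg < 90:
        raise ValueError("half_angle must be in [0, 90) degrees")
    return 2.0 * depth_um * math.tan(math.radians(half_angle_deg))


def effective_frame_rate(scanner_rate_hz: float, n_planes: int) -> float:
    """Per-plane imaging rate when a piezo steps through ``n_planes`` depths.

    A resonant scanner acquiring full frames at 60 Hz cycled over 4 planes
    samples each plane at 15 Hz.
    """
    if scanner_rate_hz <= 0:
        raise ValueError("scanner rate must be positive")
    if n_planes < 1 or int(n_planes) != n_planes:
        raise ValueError("n_planes must be a positive integer")
    return scanner_rate_hz / n_planes


def _ellipse_quadform(shape: tuple[int, int], center: tuple[float, float],
                      area_px2: float, axis_ratio: float, orientation_deg: float,
                      supersample: int = 1) -> np.ndarray:
    """(u/a)^2 + (v/b)^2 evaluated on the (optionally oversampled) grid."""
    a = math.sqrt(area_px2 * axis_ratio / math.pi)  # semi-major, px
    b = math.sqrt(area_px2 / (math.pi * axis_ratio))  # semi-minor, px
    th = math.radians(orientation_deg)
    s = supersample
    yy, xx = np.mgrid[0:shape[0] * s, 0:shape[1] * s]
    dy = (yy + 0.5) / s - 0.5 - center[0]
    dx = (xx + 0.5) / s - 0.5 - center[1]
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  area_px2: float, axis_ratio: float, orientation_deg: float) -> np.ndarray:
    """Boolean mask of a filled ellipse with the given pixel area."""
    return _ellipse_quadform(shape, center, area_px2, axis_ratio, orientation_deg) <= 1.0


def _ellipse_coverage(shape: tuple[int, int], center: tuple[float, float],
                      area_px2: float, axis_ratio: float,
                      orientation_deg: float) -> np.ndarray:
    """Per-pixel coverage fraction of the ellipse (analytic soft edge).

    Coverage is ``clip(0.5 - d, 0, 1)`` of the signed distance d (in
    pixels) to the ellipse boundary, estimated from the quadratic form
    and its gradient.  The antialiased edge keeps rendered lumen
    intensity a continuous, monotone function of the cross-section, which
    sub-pixel area changes require.
    """
    a = math.sqrt(area_px2 * axis_ratio / math.pi)
    b = math.sqrt(area_px2 / (math.pi * axis_ratio))
    th = math.radians(orientation_deg)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    g = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # 1 on the boundary
    # |grad g| with a floor to keep the centre pixel well defined
    grad = np.sqrt((u / a**2) ** 2 + (v / b**2) ** 2) / np.maximum(g, 1e-9)
    dist = (g - 1.0) / np.maximum(grad, 1e-9)
    edge = np.clip(0.5 - dist, 0.0, 1.0)
    # radial darkening profile: fully dark core, brightening toward the
    # wall (partial-volume/PSF proxy); scales with the vessel, so the
    # iso-intensity core tracks the cross-section
    profile = 1.0 - np.clip(g, 0.0, 1.0) ** 4
    return edge * profile


def _translate(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(frame, fill)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def render_frames(log: BehaviorLog, area_um2: np.ndarray,
                  config: SceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render the frame stack and record ground truth.

    Each frame is neuropil background plus bright soma disks (fluorescence
    x occlusion attenuation) and a near-dark vessel lumen ellipse whose
    pixel area tracks A(t), blurred by a Gaussian point-spread proxy.
    Poisson shot noise is applied at ``photon_scale`` photons per unit if
    enabled, then the frame is rigidly translated by the injected integer
    jitter.
    """
    rngs = _child_rngs(config.seed, 4)
    rng_geom, rng_noise = rngs[2], rngs[3]
    h, w = config.frame_shape
    n = len(log)
    px = config.pixel_size_um
    area_px2 = np.asarray(area_um2) / px**2
    vc = (config.vessel_center_um[1] / px, config.vessel_center_um[0] / px)  # (row, col)
    max_mask = _ellipse_mask((h, w), vc, float(area_px2.max()),
                             config.vessel_axis_ratio, config.vessel_orientation_deg)
    if max_mask[0, :].any() or max_mask[-1, :].any() or max_mask[:, 0].any() or max_mask[:, -1].any():
        raise ValueError("vessel ellipse exceeds frame bounds at maximal dilation")

    # place somata away from the vessel and the borders
    r_px = config.soma_radius_um / px
    margin = r_px + 2
    centers = []
    attempts = 0
    while len(centers) < config.n_somata:
        attempts += 1
        if attempts > 20000:
            raise ValueError("could not place somata within the field of view")
        c = rng_geom.uniform([margin, margin], [h - margin, w - margin])
        if max_mask[int(c[0]), int(c[1])]:
            continue
        if any(np.hypot(c[0] - o[0], c[1] - o[1]) < 2.2 * r_px for o in centers):
            continue
        centers.append(c)
    centers = np.array(centers)

    yy, xx = np.mgrid[0:h, 0:w]
    soma_masks = [
        (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2 for cy, cx in centers
    ]

    base_fluor = config.soma_baseline_fluor * rng_geom.lognormal(
        0.0, config.soma_fluor_jitter, config.n_somata)
    fluor = np.repeat(base_fluor[:, None], n, axis=1)
    if config.soma_noise_sd > 0:
        fluor = fluor * (1.0 + rng_noise.normal(0, config.soma_noise_sd,
                                                (config.n_somata, n)))
        fluor = np.clip(fluor, 0, None)

    atten = occlusion_attenuation(area_um2, config.baseline_cross_section_um2,
                                  config.occlusion_gain)
    atten = np.repeat(np.asarray(atten)[None, :], config.n_somata, axis=0)

    if config.jitter_amplitude_px > 0:
        shifts = rng_noise.integers(-config.jitter_amplitude_px,
                                    config.jitter_amplitude_px + 1, (n, 2))
    else:
        shifts = np.zeros((n, 2), dtype=int)

    stack = np.empty((n, h, w), dtype=np.float32)
    for t in range(n):
        img = np.full((h, w), config.neuropil_level, dtype=float)
        for i, m in enumerate(soma_masks):
            img[m] = fluor[i, t] * atten[i, t]
        cov = _ellipse_coverage((h, w), vc, float(area_px2[t]),
                                config.vessel_axis_ratio, config.vessel_orientation_deg)
        img = img * (1.0 - cov) + config.vessel_lumen_level * cov
        if config.psf_sigma_px > 0:
            img = ndimage.gaussian_filter(img, config.psf_sigma_px)
        if config.photon_scale > 0:
            img = rng_noise.poisson(np.clip(img, 0, None) * config.photon_scale) / config.photon_scale
        if shifts[t].any():
            img = _translate(img, int(shifts[t, 0]), int(shifts[t, 1]),
                             float(np.median(img)))
        stack[t] = img

    truth = GroundTruth(
        cross_section_um2=np.asarray(area_um2, float),
        attenuation=atten,
        soma_fluorescence=fluor,
        injected_shifts=shifts,
        soma_centers_px=centers,
        soma_radius_px=r_px,
        vessel_center_px=vc,
        vessel_axis_ratio=config.vessel_axis_ratio,
        vessel_orientation_deg=config.vessel_orientation_deg,
    )
    return stack, truth


def simulate_scene(config: SceneConfig) -> SceneData:
    """Run the full forward model: behaviour, vessel, rendered stack."""
    log = simulate_behavior(config)
    area = simulate_vessel_dynamics(log, config)
    stack, truth = render_frames(log, area, config)
    return SceneData(config=config, behavior=log, cross_section_um2=area,
                     stack=stack, truth=truth)
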