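"""Run and scene configuration.

All tunable parameters of the pipeline live in two dataclasses:
:class:`SceneConfig` (the synthetic two-photon scene) and
:class:`RunConfig` (analysis-stage parameters).  Both round-trip
losslessly through JSON/YAML dictionaries so that a run is fully
described by one file plus a seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "CouplingKernel",
    "SceneConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass
class CouplingKernel:
    """Signed vessel response kernel for one event type.

    ``amplitude`` is the fractional change in vessel cross-section at the
    kernel peak: positive for dilation, negative for constriction.  The
    kernel shape is a rise/decay double exponential normalized so that its
    discretized maximum equals ``amplitude`` exactly.
    """

    amplitude: float  # fractional cross-section change at peak
    tau_rise_s: float = 0.5
    tau_decay_s: float = 2.0

    def sample(self, frame_rate: float, duration_s: float = 15.0):
        import numpy as np

        t = np.arange(0.0, duration_s, 1.0 / frame_rate)
        shape = (1.0 - np.exp(-t / self.tau_rise_s)) * np.exp(-t / self.tau_decay_s)
        peak = shape.max()
        if peak <= 0:
            return np.zeros_like(t)
        return self.amplitude * shape / peak


@dataclass
class SceneConfig:
    """Parameters of the synthetic imaging session.

    Geometry is in micrometres; the rendered frame is
    ``field_of_view / pixel_size`` pixels.  ``occlusion_gain`` is the
    dimensionless first-order gain linking relative vessel cross-section
    change to fluorescence attenuation.  ``seed`` fixes every random draw:
    two runs with an equal config are bit-identical.
    """

    frame_rate: float = 15.0  # Hz
    duration_s: float = 300.0
    context: str = "closed_loop"  # closed_loop | open_loop | dark

    # behaviour
    locomotion_prob: float = 0.5  # probability the session starts locomoting
    mean_bout_s: float = 15.0  # exponential dwell, locomoting
    mean_rest_s: float = 20.0  # exponential dwell, stationary
    mean_speed_cmps: float = 10.0
    speed_ramp_s: float = 0.5
    grating_duration_s: float = 2.0
    grating_interval_s: float = 8.0
    mismatch_duration_s: float = 1.0
    mismatch_min_gap_s: float = 5.0
    n_mismatch: int = 8  # requested; fewer if eligible locomotion is scarce
    opto_duration_s: float = 1.0
    n_opto: int = 0

    # optics / geometry
    n_somata: int = 8
    soma_radius_um: float = 7.0
    field_of_view_um: tuple[float, float] = (128.0, 128.0)
    pixel_size_um: float = 2.0
    vessel_center_um: tuple[float, float] = (32.0, 64.0)
    vessel_axis_ratio: float = 3.0  # major/minor semi-axis ratio
    vessel_orientation_deg: float = 90.0
    baseline_cross_section_um2: float = 400.0  # A0
    vessel_area_floor_frac: float = 0.05  # floor at this fraction of A0

    # coupling kernels per event type (fractional cross-section change)
    coupling_kernels: dict[str, CouplingKernel] = field(
        default_factory=lambda: {
            "locomotion_onset": CouplingKernel(-0.10, 0.5, 3.0),
            "grating_onset": CouplingKernel(0.08, 0.5, 2.0),
            "mismatch": CouplingKernel(0.04, 0.5, 1.5),
            "opto": CouplingKernel(0.08, 0.5, 2.0),
        }
    )
    vessel_noise_sd: float = 0.0  # SD of fractional area noise per frame

    # occlusion and rendering
    occlusion_gain: float = 0.5  # k
    soma_baseline_fluor: float = 120.0  # photons/pixel at soma centre
    soma_fluor_jitter: float = 0.3  # per-soma lognormal spread of baseline
    soma_noise_sd: float = 0.0  # independent fractional fluorescence noise
    neuropil_level: float = 30.0  # photons/pixel background
    vessel_lumen_level: float = 1.0  # photons/pixel inside the vessel
    psf_sigma_px: float = 1.0
    photon_scale: float = 0.0  # 0 disables shot noise; else photons per unit
    jitter_amplitude_px: int = 0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.baseline_cross_section_um2 <= 0:
            raise ValueError("baseline cross-section A0 must be positive")
        if self.occlusion_gain < 0:
            raise ValueError("occlusion_gain k must be >= 0")
        if self.context not in ("closed_loop", "open_loop", "dark"):
            raise ValueError(f"unknown context {self.context!r}")
        kernels = {}
        for kind, k in self.coupling_kernels.items():
            kernels[kind] = k if isinstance(k, CouplingKernel) else CouplingKernel(**k)
        self.coupling_kernels = kernels
        self.field_of_view_um = tuple(self.field_of_view_um)
        self.vessel_center_um = tuple(self.vessel_center_um)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    @property
    def frame_shape(self) -> tuple[int, int]:
        h = int(round(self.field_of_view_um[1] / self.pixel_size_um))
        w = int(round(self.field_of_view_um[0] / self.pixel_size_um))
        return (h, w)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """Analysis parameters for the processing stages.

    Defaults follow the two-photon protocol: 8th-percentile drift
    correction over 66 s, onset threshold 0.25 cm/s with 1 s persistence,
    responsiveness t-test at alpha = 0.05 on the +0.5 to +1.5 s window.
    """

    baseline_window_s: float = 66.0
    baseline_percentile: float = 8.0
    registration_radius_px: int = 5

    speed_threshold_cmps: float = 0.25
    min_above_s: float = 1.0
    min_below_s: float = 1.0
    mismatch_threshold_cmps: float = 0.25
    mismatch_window_s: tuple[float, float] = (-0.5, 1.0)

    response_profile: str = "responsiveness"  # or fig2_comparison
    alpha: float = 0.05
    pre_s: float = 2.0
    post_s: float = 4.0

    n_boot_test: int = 10000
    n_boot_curve: int = 1000
    compare_alpha: float = 0.01

    vessel_percentile: float = 0.5
    smooth_width_s: float = 0.5
    r2_window_s: tuple[float, float] = (-2.0, 6.0)

    state_min_frames: int = 150

    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mismatch_window_s" in d:
            d["mismatch_window_s"] = tuple(d["mismatch_window_s"])
        if "r2_window_s" in d:
            d["r2_window_s"] = tuple(d["r2_window_s"])
        return cls(**d)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a plain dictionary."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(d: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))
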