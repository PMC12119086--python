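"""Frame registration, ROI trace extraction, and dF/F0 computation.

The processing order follows the standard two-photon protocol: rigid
full-frame registration against a reference image, mean-ROI trace
extraction (no neuropil subtraction), slow-drift correction with an
8th-percentile moving filter over 66 s, and normalization by the overall
median fluorescence F0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RoiMask",
    "DffTrace",
    "register_frames",
    "extract_roi_trace",
    "percentile_baseline",
    "compute_dff",
    "dff_pipeline",
    "time_to_frame",
    "window_to_slice",
]

ROI_KINDS = ("soma", "neuropil", "vessel_lumen", "vessel_box")


def time_to_frame(t_s: float, frame_rate: float) -> int:
    """Map a time to a frame index: frame i covers [i/rate, (i+1)/rate)."""
    return int(np.floor(t_s * frame_rate))


def window_to_slice(t0_s: float, t1_s: float, frame_rate: float) -> slice:
    """Half-open frame range for the time window [t0, t1)."""
    return slice(time_to_frame(t0_s, frame_rate), time_to_frame(t1_s, frame_rate))


@dataclass
class RoiMask:
    """A pixel region of interest in frame coordinates.

    ``kind`` distinguishes somata, neuropil patches, vessel-lumen ROIs
    (fixed boxes fully inside a vessel), and vessel boxes (vessel plus a
    neuropil margin, used for area fitting).
    """

    roi_id: str
    kind: str
    pixels: np.ndarray  # boolean mask, frame-shaped, or None if rectangle
    site_id: str = "site0"
    depth_label: str = "L2/3"
    rect: tuple[int, int, int, int] | None = None  # (y0, x0, y1, x1), half-open

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.pixels is None and self.rect is None:
            raise ValueError("RoiMask needs a pixel mask or a rectangle")

    def mask_for(self, shape: tuple[int, int]) -> np.ndarray:
        if self.pixels is not None:
            if self.pixels.shape != shape:
                raise ValueError("mask shape does not match frame shape")
            return self.pixels
        y0, x0, y1, x1 = self.rect
        if not (0 <= y0 < y1 <= shape[0] and 0 <= x0 < x1 <= shape[1]):
            raise ValueError(f"ROI {self.roi_id} rectangle outside frame bounds")
        m = np.zeros(shape, dtype=bool)
        m[y0:y1, x0:x1] = True
        return m

    @classmethod
    def from_rect(cls, roi_id: str, kind: str, y0: int, x0: int, y1: int, x1: int,
                  site_id: str = "site0", depth_label: str = "L2/3") -> "RoiMask":
        return cls(roi_id=roi_id, kind=kind, pixels=None, site_id=site_id,
                   depth_label=depth_label, rect=(y0, x0, y1, x1))


@dataclass
class DffTrace:
    """Drift-corrected, median-normalized fluorescence time series."""

    roi_id: str
    values: np.ndarray  # dF/F0 per frame, dimensionless
    frame_rate: float
    f0: float  # median raw (drift-corrected) fluorescence, a.u.

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError(f"F0 must be positive for ROI {self.roi_id}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite dF/F0 values in ROI {self.roi_id}")

    def __len__(self) -> int:
        return len(self.values)


def _shift_correlation(a: np.ndarray, b: np.ndarray, dy: int, dx: int) -> float:
    """``sum a(y + dy, x + dx) * b(y, x)`` over the valid overlap region.

    Maximal over (dy, dx) at the displacement of image ``a`` relative to
    image ``b`` (for mean-subtracted inputs).
    """
    h, w = a.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_b = slice(max(-dy, 0), min(h - dy, h))
    xs_b = slice(max(-dx, 0), min(w - dx, w))
    return float(np.sum(a[ys, xs] * b[ys_b, xs_b]))


def _best_shift(frame: np.ndarray, reference: np.ndarray, radius: int) -> tuple[int, int]:
    """Integer displacement of the frame relative to the reference that
    maximizes overlap cross-correlation within the search radius.

    Ties broken by smallest Euclidean displacement, then lexicographically.
    """
    f = frame - frame.mean()
    r = reference - reference.mean()
    if not f.any():
        logger.warning("all-constant frame: returning zero shift")
        return (0, 0)
    best = None
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            val = _shift_correlation(f, r, dy, dx)
            cand = (-val, dy * dy + dx * dx, dy, dx)
            if best is None or cand < best:
                best = cand
    return (best[2], best[3])


def register_frames(stack: np.ndarray, reference: int | np.ndarray | None = None,
                    radius: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Rigid full-frame registration to correct lateral brain motion.

    Each frame is translated by the integer shift that maximizes its
    cross-correlation with the reference (a frame index, an image, or the
    stack mean) within ``radius`` pixels.  Out-of-frame pixels are filled
    with the frame median.  Returns the registered stack and the per-frame
    (dy, dx) shifts applied.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    if reference is None:
        ref = stack.mean(axis=0)
    elif isinstance(reference, (int, np.integer)):
        ref = stack[int(reference)]
    else:
        ref = np.asarray(reference, float)
    out = np.empty_like(stack)
    shifts = np.zeros((stack.shape[0], 2), dtype=int)
    from .synthetic import _translate

    for t in range(stack.shape[0]):
        dy, dx = _best_shift(stack[t], ref, radius)
        shifts[t] = (dy, dx)  # detected displacement of the frame
        if dy or dx:
            out[t] = _translate(stack[t], -dy, -dx, float(np.median(stack[t])))
        else:
            out[t] = stack[t]
    return out, shifts


def extract_roi_trace(stack: np.ndarray, mask: RoiMask) -> np.ndarray:
    """Per-frame arithmetic mean of the pixels in the ROI.

    No neuropil subtraction is applied.
    """
    m = mask.mask_for(stack.shape[1:])
    if not m.any():
        raise ValueError(f"ROI {mask.roi_id} has an empty mask")
    return stack[:, m].mean(axis=1)


def percentile_baseline(trace: np.ndarray, frame_rate: float,
                        window_s: float = 66.0, percentile: float = 8.0) -> np.ndarray:
    """Moving-percentile baseline for slow drift (8th percentile over 66 s).

    The window is centred on each frame and truncated at the recording
    edges.  The widefield variant (62.5 s) is obtained via ``window_s``.
    """
    trace = np.asarray(trace, float)
    n = len(trace)
    if n < 3:
        raise ValueError("trace must have at least 3 frames")
    w = max(3, int(round(window_s * frame_rate)))
    half = w // 2
    w = 2 * half + 1  # symmetric, centred window
    out = np.empty(n)
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        interior = np.percentile(sliding_window_view(trace, w), percentile, axis=1)
        out[half:half + len(interior)] = interior
        edge = list(range(half)) + list(range(half + len(interior), n))
    else:
        edge = range(n)
    for i in edge:
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.percentile(trace[lo:hi], percentile)
    return out


def compute_dff(trace: np.ndarray, baseline: np.ndarray, frame_rate: float,
                roi_id: str = "roi") -> DffTrace:
    """dF/F0 from a raw trace and its slow baseline.

    The baseline is subtracted and its mean re-added so the corrected
    trace keeps the absolute scale; F0 is the overall median of the
    corrected trace and dF/F0 = (F_c - F0) / F0.
    """
    trace = np.asarray(trace, float)
    corrected = trace - baseline + baseline.mean()
    f0 = float(np.median(corrected))
    if f0 <= 0:
        raise ValueError(f"non-positive median fluorescence F0 for ROI {roi_id}")
    return DffTrace(roi_id=roi_id, values=(corrected - f0) / f0,
                    frame_rate=frame_rate, f0=f0)


def dff_pipeline(stack: np.ndarray, rois: list[RoiMask], frame_rate: float,
                 window_s: float = 66.0, percentile: float = 8.0,
                 register: bool = True, radius: int = 5
                 ) -> tuple[dict[str, DffTrace], np.ndarray]:
    """Registration + extraction + drift correction for a set of ROIs."""
    if register:
        stack, shifts = register_frames(stack, radius=radius)
    else:
        shifts = np.zeros((stack.shape[0], 2), dtype=int)
    traces = {}
    for roi in rois:
        raw = extract_roi_trace(stack, roi)
        base = percentile_baseline(raw, frame_rate, window_s, percentile)
        traces[roi.roi_id] = compute_dff(raw, base, frame_rate, roi.roi_id)
    return traces, shifts
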