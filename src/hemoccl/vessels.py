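"""Blood-vessel cross-section estimation and variance attribution.

The vessel lumen carries essentially no fluorescence, so in a
trial-averaged video it appears as a dark region.  Binarizing the
cropped video at the 0.5th percentile of all its pixel intensities and
fitting an ellipse to the largest connected below-threshold component
gives a per-frame cross-section estimate (area = pi * a * b).  A
complementary proxy that avoids thresholding is the mean fluorescence of
a small ROI fixed inside the lumen: as the vessel constricts, more of
the surrounding labelled tissue enters the point spread function and the
lumen signal rises, so proxy and area are anticorrelated.  Variance
explained between vessel and neuronal signals is the squared Pearson
correlation after 0.5 s boxcar smoothing, on the -2 to +6 s peri-event
window or over the whole recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

from .preprocess import RoiMask, compute_dff, extract_roi_trace, percentile_baseline, window_to_slice

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseFit",
    "VesselMeasurement",
    "vessel_area_trace",
    "vessel_lumen_trace",
    "moving_average",
    "variance_explained",
    "iqr_outlier_mask",
]


@dataclass
class EllipseFit:
    centroid: tuple[float, float]  # (row, col) within the cropped box
    semi_major: float
    semi_minor: float
    orientation_rad: float
    area: float  # pi * a * b, px^2
    touches_edge: bool


@dataclass
class VesselMeasurement:
    vessel_id: str
    area_px2: np.ndarray
    ellipses: list[EllipseFit | None]
    lumen_dff: np.ndarray | None = None


def _fit_ellipse(binary: np.ndarray) -> EllipseFit | None:
    """Moment-matched ellipse on the largest 8-connected component.

    Second central moments include the 1/12 per-pixel (square-pixel)
    correction, so single-pixel and collinear components still yield a
    ellipse of roughly their pixel count rather than a degenerate one.
    """
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return None
    counts = np.bincount(labels.ravel())[1:]
    ys, xs = np.nonzero(labels == (np.argmax(counts) + 1))
    cy, cx = ys.mean(), xs.mean()
    mu_yy = np.mean((ys - cy) ** 2) + 1.0 / 12.0
    mu_xx = np.mean((xs - cx) ** 2) + 1.0 / 12.0
    mu_xy = np.mean((ys - cy) * (xs - cx))
    common = np.sqrt((mu_xx - mu_yy) ** 2 + 4.0 * mu_xy**2)
    a = np.sqrt(2.0 * (mu_xx + mu_yy + common))
    b = np.sqrt(2.0 * (mu_xx + mu_yy - common))
    orientation = 0.5 * np.arctan2(2.0 * mu_xy, mu_xx - mu_yy)
    touches = (ys.min() == 0 or xs.min() == 0
               or ys.max() == binary.shape[0] - 1 or xs.max() == binary.shape[1] - 1)
    return EllipseFit(centroid=(float(cy), float(cx)), semi_major=float(a),
                      semi_minor=float(b), orientation_rad=float(orientation),
                      area=float(np.pi * a * b), touches_edge=touches)


def vessel_area_trace(stack: np.ndarray, vessel_box: RoiMask | None = None,
                      percentile: float = 0.5, vessel_id: str = "vessel"
                      ) -> VesselMeasurement:
    """Per-frame vessel cross-section from a trial-averaged video.

    A single global threshold — the ``percentile``-th percentile of all
    pixel intensities of the (cropped) video — binarizes every frame;
    the largest below-threshold connected component is summarized by a
    moment-matched ellipse whose area pi*a*b estimates the cross-section.
    Frames with no below-threshold pixels get area 0 with a warning;
    components touching the box edge are flagged as possibly truncated.
    """
    stack = np.asarray(stack, float)
    if vessel_box is not None:
        if vessel_box.rect is not None:
            y0, x0, y1, x1 = vessel_box.rect
            stack = stack[:, y0:y1, x0:x1]
        else:
            m = vessel_box.mask_for(stack.shape[1:])
            ys, xs = np.nonzero(m)
            stack = stack[:, ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    threshold = np.percentile(stack, percentile)  # once, over the whole video
    areas = np.empty(stack.shape[0])
    ellipses: list[EllipseFit | None] = []
    n_edge = 0
    for t in range(stack.shape[0]):
        fit = _fit_ellipse(stack[t] < threshold)
        if fit is None:
            logger.warning("frame %d: no below-threshold pixels; area set to 0", t)
            areas[t] = 0.0
        else:
            areas[t] = fit.area
            n_edge += fit.touches_edge
        ellipses.append(fit)
    if n_edge:
        logger.warning("vessel component touches the box edge in %d frames "
                       "(possible truncation)", n_edge)
    return VesselMeasurement(vessel_id=vessel_id, area_px2=areas, ellipses=ellipses)


def vessel_lumen_trace(stack: np.ndarray, lumen_roi: RoiMask, frame_rate: float,
                       window_s: float = 66.0, percentile: float = 8.0) -> np.ndarray:
    """dF/F0 of a fixed ROI inside the vessel lumen.

    Runs the standard extraction pipeline on the lumen ROI.  The signal
    rises as the vessel constricts and falls as it dilates, providing a
    threshold-free proxy for cross-section changes.
    """
    raw = extract_roi_trace(stack, lumen_roi)
    base = percentile_baseline(raw, frame_rate, window_s, percentile)
    return compute_dff(raw, base, frame_rate, lumen_roi.roi_id).values


def moving_average(series: np.ndarray, frame_rate: float,
                   width_s: float = 0.5) -> np.ndarray:
    """Centred boxcar smoothing, width rounded to the nearest odd frame
    count, truncated at the edges."""
    x = np.asarray(series, float)
    w = max(1, int(round(width_s * frame_rate)))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return x.copy()
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def variance_explained(x: np.ndarray, y: np.ndarray, frame_rate: float | None = None,
                       window_s: tuple[float, float] | None = None,
                       onset_frame: int | None = None) -> float:
    """Squared Pearson correlation between two signals (R^2).

    With ``window_s`` and ``onset_frame`` given, the correlation is
    computed on the mapped peri-event window (default use: -2 to +6 s
    around stimulus onset on trial-averaged signals); otherwise on the
    full series ("entire recording" mode).  Returns NaN when either
    signal has zero variance in the window.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if window_s is not None:
        if frame_rate is None or onset_frame is None:
            raise ValueError("window mode needs frame_rate and onset_frame")
        sl = window_to_slice(window_s[0], window_s[1], frame_rate)
        sl = slice(sl.start + onset_frame, sl.stop + onset_frame)
        if sl.start < 0 or sl.stop > len(x):
            raise ValueError("R^2 window falls outside the series")
        x, y = x[sl], y[sl]
    if len(x) != len(y):
        raise ValueError("series must have equal length in the window")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance: variance explained undefined")
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def iqr_outlier_mask(values: np.ndarray) -> np.ndarray:
    """Tukey fences: True where outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Used only for display-level omission of points, never for statistics.
    """
    v = np.asarray(values, float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for quartile fences")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v > q3 + 1.5 * iqr) | (v < q1 - 1.5 * iqr)
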