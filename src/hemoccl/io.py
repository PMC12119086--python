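"""Readers and writers for the pipeline's on-disk formats.

Frame stacks are multi-page 16-bit TIFF; behaviour logs, ground truth,
ROI rectangles, traces, and events are headered CSV; per-run metadata is
JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .events import EventSet
from .preprocess import DffTrace, RoiMask
from .synthetic import BehaviorLog, GroundTruth

__all__ = [
    "write_stack",
    "read_stack",
    "write_behavior",
    "read_behavior",
    "write_truth",
    "read_truth",
    "write_rois",
    "read_rois",
    "read_roi_labels",
    "write_traces",
    "read_traces",
    "write_events",
    "read_events",
]


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (T, H, W) stack as multi-page 16-bit TIFF (values rounded)."""
    data = np.clip(np.round(np.asarray(stack)), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), data.astype(np.uint16), photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return np.asarray(stack, float)


def write_behavior(log: BehaviorLog, path: str | Path) -> None:
    log.to_frame().to_csv(path, index=False)


def read_behavior(path: str | Path, frame_rate: float | None = None) -> BehaviorLog:
    return BehaviorLog.from_frame(pd.read_csv(path), frame_rate)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_rois(rois: list[RoiMask], path: str | Path) -> None:
    """Rectangle ROI list as CSV (0-based, half-open coordinates)."""
    rows = []
    for r in rois:
        if r.rect is None:
            raise ValueError(f"ROI {r.roi_id} has no rectangle; use a label-mask TIFF")
        y0, x0, y1, x1 = r.rect
        rows.append({"roi_id": r.roi_id, "kind": r.kind, "site_id": r.site_id,
                     "depth_label": r.depth_label,
                     "y0": y0, "x0": x0, "y1": y1, "x1": x1})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rois(path: str | Path) -> list[RoiMask]:
    df = pd.read_csv(path)
    return [
        RoiMask.from_rect(str(r.roi_id), str(r.kind), int(r.y0), int(r.x0),
                          int(r.y1), int(r.x1), site_id=str(r.site_id),
                          depth_label=str(r.depth_label))
        for r in df.itertuples()
    ]


def read_roi_labels(path: str | Path, kind: str = "soma",
                    site_id: str = "site0") -> list[RoiMask]:
    """ROIs from a label-mask TIFF: one ROI per nonzero label value."""
    labels = tifffile.imread(str(path))
    rois = []
    for value in np.unique(labels):
        if value == 0:
            continue
        rois.append(RoiMask(roi_id=f"roi{int(value)}", kind=kind,
                            pixels=labels == value, site_id=site_id))
    return rois


def write_traces(traces: dict[str, DffTrace], path: str | Path,
                 shifts: np.ndarray | None = None) -> None:
    """Traces CSV (one column per ROI) plus a JSON sidecar with F0,
    frame rate, and registration shifts."""
    path = Path(path)
    df = pd.DataFrame({rid: t.values for rid, t in traces.items()})
    df.to_csv(path, index=False)
    meta = {
        "frame_rate": next(iter(traces.values())).frame_rate if traces else None,
        "f0": {rid: t.f0 for rid, t in traces.items()},
        "shifts": None if shifts is None else np.asarray(shifts).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_traces(path: str | Path) -> dict[str, DffTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return {
        rid: DffTrace(roi_id=rid, values=df[rid].to_numpy(float),
                      frame_rate=float(meta["frame_rate"]),
                      f0=float(meta["f0"][rid]))
        for rid in df.columns
    }


def write_events(events: EventSet, path: str | Path) -> None:
    path = Path(path)
    events.to_frame().to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(events.provenance, indent=2))


def read_events(path: str | Path) -> EventSet:
    path = Path(path)
    prov = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
    return EventSet.from_frame(pd.read_csv(path), prov)
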