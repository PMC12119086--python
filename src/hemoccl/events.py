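"""Event onset detection and behavioural state masks.

Locomotion onsets follow the threshold-and-persistence rule used
throughout the analysis: running speed crosses 0.25 cm/s and stays at or
above it for at least 1 s, after having been strictly below the
threshold for the whole preceding 1 s.  The same rule applied to the
visual-flow speed yields visual-flow onsets.  Mismatch events are
validated by requiring uninterrupted locomotion from -0.5 s to +1 s
around the onset; random triggers are drawn from frames satisfying the
same eligibility rule to build chance distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EVENT_KINDS",
    "Event",
    "EventSet",
    "detect_onsets",
    "validate_mismatch_events",
    "sample_random_locomotion_triggers",
    "locomotion_state_mask",
    "detect_all_events",
]

EVENT_KINDS = (
    "locomotion_onset",
    "visual_flow_onset",
    "grating_onset",
    "mismatch",
    "opto",
    "random_trigger",
)

SPEED_THRESHOLD_CMPS = 0.25  # canonical locomotion threshold


@dataclass
class Event:
    kind: str
    frame: int
    time_s: float


@dataclass
class EventSet:
    """Validated event onsets with the rule parameters that produced them."""

    events: list[Event]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind in {e.kind for e in self.events}:
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {kind!r}")
            frames = self.frames(kind)
            if np.any(np.diff(frames) <= 0):
                raise ValueError(f"onsets of kind {kind!r} not strictly increasing")

    def frames(self, kind: str) -> np.ndarray:
        return np.array([e.frame for e in self.events if e.kind == kind], dtype=int)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"kind": e.kind, "frame": e.frame, "time_s": e.time_s} for e in self.events]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "EventSet":
        events = [Event(str(r.kind), int(r.frame), float(r.time_s))
                  for r in df.itertuples()]
        return cls(events=events, provenance=provenance or {})


def detect_onsets(speed: np.ndarray, frame_rate: float,
                  threshold: float = SPEED_THRESHOLD_CMPS,
                  min_above_s: float = 1.0, min_below_s: float = 1.0) -> np.ndarray:
    """Onset frames by the threshold-and-persistence rule.

    Frame f is an onset iff ``speed[f] >= threshold``, the speed was
    strictly below the threshold at every frame of the preceding
    ``min_below_s`` window, and stays at or above it for every frame of
    ``[f, f + min_above_s)``.  The rule itself enforces a refractory
    period of ``min_below_s`` between onsets.
    """
    speed = np.asarray(speed, float)
    n_above = int(round(min_above_s * frame_rate))
    n_below = int(round(min_below_s * frame_rate))
    n = len(speed)
    if n < n_above + n_below:
        logger.warning("series shorter than the onset rule windows; no onsets")
        return np.array([], dtype=int)
    above = speed >= threshold
    # rolling all-true counts via cumulative sums of the boolean series
    ca = np.r_[0, np.cumsum(above)]
    cb = np.r_[0, np.cumsum(~above)]
    onsets = []
    for f in range(n_below, n - n_above + 1):
        if (ca[f + n_above] - ca[f]) == n_above and (cb[f] - cb[f - n_below]) == n_below:
            onsets.append(f)
    return np.array(onsets, dtype=int)


def validate_mismatch_events(mismatch_on: np.ndarray, speed: np.ndarray,
                             frame_rate: float,
                             threshold: float = SPEED_THRESHOLD_CMPS,
                             window_s: tuple[float, float] = (-0.5, 1.0)
                             ) -> np.ndarray:
    """Mismatch onsets retained only under uninterrupted locomotion.

    An onset (first frame of each contiguous flag run) is kept iff the
    running speed is at or above the threshold at every frame of the
    validity window (default -0.5 s to +1 s).  A relaxed threshold (0.12
    cm/s, used when triggers are scarce) can be passed instead.
    """
    flags = np.asarray(mismatch_on, bool)
    speed = np.asarray(speed, float)
    if len(flags) != len(speed):
        raise ValueError("mismatch flags and speed must be aligned")
    onsets = np.flatnonzero(flags & ~np.r_[False, flags[:-1]])
    pre = int(round(-window_s[0] * frame_rate))
    post = int(round(window_s[1] * frame_rate))
    kept = []
    for f in onsets:
        if f - pre < 0 or f + post > len(speed):
            logger.info("mismatch at frame %d dropped: window outside recording", f)
            continue
        if np.all(speed[f - pre:f + post] >= threshold):
            kept.append(int(f))
    return np.array(kept, dtype=int)


def _eligible_trigger_frames(speed: np.ndarray, frame_rate: float,
                             threshold: float,
                             window_s: tuple[float, float]) -> np.ndarray:
    pre = int(round(-window_s[0] * frame_rate))
    post = int(round(window_s[1] * frame_rate))
    above = speed >= threshold
    c = np.r_[0, np.cumsum(above)]
    n = len(speed)
    frames = np.arange(pre, n - post + 1)
    if len(frames) == 0:
        return frames
    ok = (c[frames + post] - c[frames - pre]) == (pre + post)
    return frames[ok]


def sample_random_locomotion_triggers(speed: np.ndarray, frame_rate: float,
                                      n_triggers: int,
                                      threshold: float = SPEED_THRESHOLD_CMPS,
                                      window_s: tuple[float, float] = (-0.5, 1.0),
                                      seed: int | np.random.Generator = 0,
                                      exclude_onsets: np.ndarray | None = None,
                                      exclusion_s: float = 1.0) -> np.ndarray:
    """Random triggers during locomotion for chance-level estimation.

    Uniform sample without replacement from all frames satisfying the
    mismatch validity rule, excluding frames within ``exclusion_s`` of a
    true mismatch onset.  Seeded and reproducible.
    """
    eligible = _eligible_trigger_frames(np.asarray(speed, float), frame_rate,
                                        threshold, window_s)
    if exclude_onsets is not None and len(exclude_onsets):
        excl = int(round(exclusion_s * frame_rate))
        mask = np.ones(len(eligible), bool)
        for f in np.asarray(exclude_onsets):
            mask &= np.abs(eligible - f) > excl
        eligible = eligible[mask]
    if len(eligible) < n_triggers:
        raise ValueError(
            f"only {len(eligible)} eligible trigger frames for {n_triggers} requested")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.sort(rng.choice(eligible, size=n_triggers, replace=False))


def locomotion_state_mask(speed: np.ndarray,
                          threshold: float = SPEED_THRESHOLD_CMPS) -> np.ndarray:
    """Per-frame behavioural state: True where locomoting (no hysteresis)."""
    return np.asarray(speed, float) >= threshold


def detect_all_events(behavior, threshold: float = SPEED_THRESHOLD_CMPS,
                      mismatch_threshold: float = SPEED_THRESHOLD_CMPS,
                      min_above_s: float = 1.0, min_below_s: float = 1.0,
                      mismatch_window_s: tuple[float, float] = (-0.5, 1.0)
                      ) -> EventSet:
    """Full event inventory from a behaviour log.

    Locomotion and visual-flow onsets come from the threshold rule;
    grating and opto onsets are rising edges of their stimulus flags;
    mismatch onsets are flag edges validated by the locomotion rule.
    """
    rate = behavior.frame_rate
    events: list[Event] = []

    def add(kind: str, frames: np.ndarray) -> None:
        events.extend(Event(kind, int(f), float(f / rate)) for f in frames)

    add("locomotion_onset", detect_onsets(behavior.running_speed_cmps, rate,
                                          threshold, min_above_s, min_below_s))
    add("visual_flow_onset", detect_onsets(behavior.visual_flow_cmps, rate,
                                           threshold, min_above_s, min_below_s))
    grating = np.asarray(behavior.grating_on, bool)
    add("grating_onset", np.flatnonzero(grating & ~np.r_[False, grating[:-1]]))
    opto = np.asarray(behavior.opto_on, bool)
    add("opto", np.flatnonzero(opto & ~np.r_[False, opto[:-1]]))
    add("mismatch", validate_mismatch_events(behavior.mismatch_on,
                                             behavior.running_speed_cmps, rate,
                                             mismatch_threshold, mismatch_window_s))
    prov = {
        "threshold_cmps": threshold,
        "mismatch_threshold_cmps": mismatch_threshold,
        "min_above_s": min_above_s,
        "min_below_s": min_below_s,
        "mismatch_window_s": list(mismatch_window_s),
    }
    return EventSet(events=events, provenance=prov)
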