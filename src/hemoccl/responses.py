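"""Event-triggered responses and per-neuron responsiveness statistics.

The analysis chain mirrors the standard protocol: slice a peri-event
window around each validated onset, subtract a pre-onset baseline
(-0.5 to 0 s; -1 to -0.5 s for locomotion, to avoid preparatory
activity), average each trial over a response window (+0.5 to +1.5 s
for locomotion/mismatch, +0.5 to +2.5 s for 2 s gratings), and test the
per-trial means against zero with a two-sided one-sample t-test at
alpha = 0.05.  ROIs with fewer than three complete trials are excluded.
A random-trigger resampling of the population average provides the 95%
chance band used to judge mismatch responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import DffTrace, time_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "WINDOW_PROFILES",
    "TrialMatrix",
    "ResponsivenessResult",
    "event_triggered_matrix",
    "baseline_subtract",
    "trial_mean_response",
    "test_responsive",
    "responsive_fraction",
    "chance_interval_from_random_triggers",
    "MIN_TRIALS",
]

MIN_TRIALS = 3  # inclusion rule: at least three onsets per ROI and event

# (baseline window, response window) in seconds relative to onset, per
# event kind.  "responsiveness" is the per-neuron test profile;
# "fig2_comparison" is the indicator-comparison profile.
WINDOW_PROFILES: dict[str, dict[str, tuple[tuple[float, float], tuple[float, float]]]] = {
    "responsiveness": {
        "locomotion_onset": ((-1.0, -0.5), (0.5, 1.5)),
        "visual_flow_onset": ((-0.5, 0.0), (0.5, 1.5)),
        "mismatch": ((-0.5, 0.0), (0.5, 1.5)),
        "random_trigger": ((-0.5, 0.0), (0.5, 1.5)),
        "grating_onset": ((-0.5, 0.0), (0.5, 2.5)),
        "opto": ((-0.5, 0.0), (0.5, 1.5)),
    },
    "fig2_comparison": {
        "locomotion_onset": ((-1.0, -0.5), (0.0, 2.0)),
        "mismatch": ((-1.0, -0.5), (0.0, 2.0)),
        "grating_onset": ((-0.5, 0.0), (0.5, 3.0)),
    },
}


@dataclass
class TrialMatrix:
    """Trials x time-bins slice of one ROI's dF/F0 around event onsets."""

    roi_id: str
    kind: str
    data: np.ndarray  # (n_trials, n_bins)
    time_s: np.ndarray  # bin centres relative to onset
    frame_rate: float
    frame_offset: int = 0  # frame index of column 0 relative to onset (negative)
    baseline_window_s: tuple[float, float] | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def included(self) -> bool:
        return self.n_trials >= MIN_TRIALS


@dataclass
class ResponsivenessResult:
    roi_id: str
    kind: str
    trial_means: np.ndarray
    t_stat: float
    p_value: float
    responsive: bool
    alpha: float = 0.05


def event_triggered_matrix(trace: DffTrace, onset_frames: np.ndarray, kind: str,
                           pre_s: float = 2.0, post_s: float = 4.0) -> TrialMatrix:
    """Per-trial peri-event slices of a dF/F0 trace.

    Events whose window extends outside the recording are dropped and
    logged; a matrix with fewer than three surviving trials is flagged as
    excluded from further analysis.
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValueError("pre and post windows must be positive")
    rate = trace.frame_rate
    lo = time_to_frame(-pre_s, rate)
    hi = time_to_frame(post_s, rate)
    n = len(trace.values)
    rows = []
    for f in np.asarray(onset_frames, int):
        if f + lo < 0 or f + hi > n:
            logger.info("event at frame %d dropped: incomplete window", f)
            continue
        rows.append(trace.values[f + lo:f + hi])
    data = np.array(rows) if rows else np.empty((0, hi - lo))
    if len(onset_frames) == 0:
        logger.warning("no events of kind %s for ROI %s", kind, trace.roi_id)
    time_s = (np.arange(lo, hi) + 0.5) / rate
    return TrialMatrix(roi_id=trace.roi_id, kind=kind, data=data,
                       time_s=time_s, frame_rate=rate, frame_offset=lo)


def _window_cols(matrix: TrialMatrix, window_s: tuple[float, float]) -> np.ndarray:
    rate = matrix.frame_rate
    a = time_to_frame(window_s[0], rate) - matrix.frame_offset
    b = time_to_frame(window_s[1], rate) - matrix.frame_offset
    cols = np.arange(a, b)
    if len(cols) == 0 or cols[0] < 0 or cols[-1] >= matrix.data.shape[1]:
        raise ValueError(f"window {window_s} falls outside the trial matrix")
    return cols


def baseline_subtract(matrix: TrialMatrix,
                      baseline_window_s: tuple[float, float] | None = None,
                      profile: str = "responsiveness") -> TrialMatrix:
    """Subtract each trial's pre-onset baseline mean from its row.

    The default window per event kind comes from the named profile
    (locomotion uses -1 to -0.5 s; the others -0.5 to 0 s).
    """
    if baseline_window_s is None:
        baseline_window_s = WINDOW_PROFILES[profile][matrix.kind][0]
    if baseline_window_s[1] > 0 or baseline_window_s[0] >= baseline_window_s[1]:
        raise ValueError("baseline window must be a nonempty interval ending at or before onset")
    cols = _window_cols(matrix, baseline_window_s)
    base = matrix.data[:, cols].mean(axis=1, keepdims=True) if matrix.n_trials else 0.0
    return TrialMatrix(roi_id=matrix.roi_id, kind=matrix.kind,
                       data=matrix.data - base, time_s=matrix.time_s,
                       frame_rate=matrix.frame_rate, frame_offset=matrix.frame_offset,
                       baseline_window_s=tuple(baseline_window_s))


def trial_mean_response(matrix: TrialMatrix,
                        response_window_s: tuple[float, float] | None = None,
                        profile: str = "responsiveness") -> np.ndarray:
    """Per-trial scalar response: mean over the response window."""
    if response_window_s is None:
        response_window_s = WINDOW_PROFILES[profile][matrix.kind][1]
    cols = _window_cols(matrix, response_window_s)
    return matrix.data[:, cols].mean(axis=1)


def test_responsive(trial_means: np.ndarray, alpha: float = 0.05,
                    roi_id: str = "roi", kind: str = "locomotion_onset"
                    ) -> ResponsivenessResult:
    """Two-sided one-sample t-test of the per-trial means against zero."""
    x = np.asarray(trial_means, float)
    if len(x) < MIN_TRIALS:
        raise ValueError(f"need at least {MIN_TRIALS} trials, got {len(x)}")
    if np.ptp(x) == 0:
        if x[0] == 0:
            t, p = 0.0, 1.0
        else:  # zero variance around a nonzero mean: maximally significant
            t = np.inf if x[0] > 0 else -np.inf
            p = np.finfo(float).tiny
    else:
        t, p = stats.ttest_1samp(x, 0.0)
    return ResponsivenessResult(roi_id=roi_id, kind=kind, trial_means=x,
                                t_stat=float(t), p_value=float(p),
                                responsive=bool(p < alpha), alpha=alpha)


def responsive_fraction(site_results: dict[str, list[ResponsivenessResult]],
                        chance_level: float = 0.05
                        ) -> tuple[dict[str, float], float, float]:
    """Per-site responsive fractions and an across-site test against chance.

    Returns (fractions per site, t statistic, p value) of a one-sample
    t-test of the site fractions against the nominal chance level.
    """
    fractions = {}
    for site, results in site_results.items():
        if len(results) == 0:
            logger.info("site %s omitted: no tested ROIs", site)
            continue
        fractions[site] = float(np.mean([r.responsive for r in results]))
    if not fractions:
        raise ValueError("no sites with tested ROIs")
    vals = np.array(list(fractions.values()))
    if len(vals) < 2 or np.ptp(vals) == 0:
        t, p = np.nan, np.nan
    else:
        t, p = stats.ttest_1samp(vals, chance_level)
    return fractions, float(t), float(p)


def chance_interval_from_random_triggers(traces: list[DffTrace], speed: np.ndarray,
                                         n_triggers: int, n_rep: int,
                                         pre_s: float = 2.0, post_s: float = 4.0,
                                         threshold: float = 0.25,
                                         window_s: tuple[float, float] = (-0.5, 1.0),
                                         exclude_onsets: np.ndarray | None = None,
                                         seed: int = 0,
                                         profile_kind: str = "random_trigger"
                                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-time-bin 95% chance band from random locomotion triggers.

    Repeats ``n_rep`` times: draw a random trigger set eligible under the
    mismatch validity rule, compute the baseline-subtracted population
    event-triggered average, and collect it.  The band is the per-bin
    2.5th-97.5th percentile across repetitions.  Returns
    (time axis, lower, upper).
    """
    from .events import sample_random_locomotion_triggers

    if n_rep < 40:
        raise ValueError("n_rep < 40 gives an unreliable 95% band")
    rng = np.random.default_rng(seed)
    rate = traces[0].frame_rate
    curves = []
    time_s = None
    for _ in range(n_rep):
        triggers = sample_random_locomotion_triggers(
            speed, rate, n_triggers, threshold, window_s, rng,
            exclude_onsets=exclude_onsets)
        pop = []
        for tr in traces:
            m = event_triggered_matrix(tr, triggers, profile_kind, pre_s, post_s)
            if not m.included:
                continue
            m = baseline_subtract(m)
            pop.append(m.data.mean(axis=0))
            time_s = m.time_s
        if pop:
            curves.append(np.mean(pop, axis=0))
    if not curves:
        raise ValueError("no complete random-trigger windows available")
    curves = np.array(curves)
    lo = np.percentile(curves, 2.5, axis=0)
    hi = np.percentile(curves, 97.5, axis=0)
    return time_s, lo, hi
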