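"""State-dependent pairwise correlation structure.

Hemodynamic occlusion is a shared multiplicative signal: when a surface
vessel dilates, every neuron beneath it darkens together.  A signature
of this is that pairwise correlations between simultaneously imaged
neurons rise during locomotion (when vessels are driven) relative to
stationary periods.  Correlations are computed per behavioural state by
restricting each pair of dF/F0 traces to the frames of that state
(concatenated across the session) and averaging each neuron's Pearson
correlation over all its same-site pairings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["StateCorrelation", "pairwise_state_correlations", "state_correlation_table"]

MIN_STATE_FRAMES = 150  # 10 s at 15 Hz


@dataclass
class StateCorrelation:
    roi_id: str
    corr_stationary: float
    corr_locomoting: float
    n_frames_stationary: int
    n_frames_locomoting: int


def _mean_offdiag_corr(data: np.ndarray) -> np.ndarray:
    """Per-row mean Pearson correlation to all other rows.

    Rows with zero variance yield NaN (their pairings are undefined).
    """
    sd = data.std(axis=1)
    ok = sd > 0
    n = data.shape[0]
    out = np.full(n, np.nan)
    if ok.sum() < 2:
        return out
    c = np.corrcoef(data[ok])
    np.fill_diagonal(c, np.nan)
    mean_ok = np.nanmean(c, axis=1)
    out[ok] = mean_ok
    # a ROI keeps its value only if it has at least one valid pairing
    return out


def pairwise_state_correlations(traces: dict[str, np.ndarray],
                                state_mask: np.ndarray,
                                min_frames: int = MIN_STATE_FRAMES
                                ) -> list[StateCorrelation]:
    """Mean pairwise correlation of each ROI to its site mates, per state.

    ``traces`` maps roi_id to a dF/F0 array (one imaging site);
    ``state_mask`` is True where locomoting.  Sites lacking
    ``min_frames`` in either state are skipped with a log entry.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 ROIs per site")
    ids = list(traces.keys())
    data = np.vstack([np.asarray(traces[i], float) for i in ids])
    mask = np.asarray(state_mask, bool)
    if data.shape[1] != len(mask):
        raise ValueError("state mask not aligned with traces")
    n_loc = int(mask.sum())
    n_sta = int((~mask).sum())
    if n_loc < min_frames or n_sta < min_frames:
        logger.info("site skipped: %d locomoting / %d stationary frames "
                    "(need %d)", n_loc, n_sta, min_frames)
        return []
    corr_sta = _mean_offdiag_corr(data[:, ~mask])
    corr_loc = _mean_offdiag_corr(data[:, mask])
    return [
        StateCorrelation(roi_id=ids[i], corr_stationary=float(corr_sta[i]),
                         corr_locomoting=float(corr_loc[i]),
                         n_frames_stationary=n_sta, n_frames_locomoting=n_loc)
        for i in range(len(ids))
    ]


def state_correlation_table(per_site: dict[str, list[StateCorrelation]]) -> pd.DataFrame:
    rows = []
    for site_id, results in per_site.items():
        for r in results:
            rows.append({
                "site_id": site_id,
                "roi_id": r.roi_id,
                "corr_stationary": r.corr_stationary,
                "corr_locomoting": r.corr_locomoting,
                "n_frames_stationary": r.n_frames_stationary,
                "n_frames_locomoting": r.n_frames_locomoting,
            })
    return pd.DataFrame(rows)
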