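"""Independent oracles shared by the test modules.

These reimplement textual rules directly (brute force, literal scans)
and stay independent of the library code paths they validate.
"""

import numpy as np


def brute_force_onsets(speed, rate, threshold=0.25, min_above_s=1.0, min_below_s=1.0):
    """Literal per-frame evaluation of the locomotion onset rule."""
    n_above = int(round(min_above_s * rate))
    n_below = int(round(min_below_s * rate))
    onsets = []
    for f in range(len(speed)):
        if f - n_below < 0 or f + n_above > len(speed):
            continue
        if all(speed[j] < threshold for j in range(f - n_below, f)) and \
           all(speed[j] >= threshold for j in range(f, f + n_above)):
            onsets.append(f)
    return np.array(onsets, dtype=int)


def exhaustive_shift_search(frame, reference, radius):
    """Vectorized exhaustive search for the displacement maximizing the
    overlap cross-correlation of mean-subtracted images."""
    f = frame - frame.mean()
    r = reference - reference.mean()
    h, w = frame.shape
    best, best_key = None, None
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            a = f[max(dy, 0):min(h + dy, h), max(dx, 0):min(w + dx, w)]
            b = r[max(-dy, 0):min(h - dy, h), max(-dx, 0):min(w - dx, w)]
            val = float((a * b).sum())
            key = (-val, dy * dy + dx * dx, dy, dx)
            if best is None or key < best_key:
                best, best_key = (dy, dx), key
    return best
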