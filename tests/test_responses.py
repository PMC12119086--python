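"""Event-triggered windows, responsiveness tests, and chance bands."""

import numpy as np
import pytest

from hemoccl import (
    DffTrace,
    baseline_subtract,
    chance_interval_from_random_triggers,
    event_triggered_matrix,
    responsive_fraction,
    trial_mean_response,
)
from hemoccl.responses import WINDOW_PROFILES
from hemoccl.responses import test_responsive as responsiveness_ttest

RATE = 15.0


def _trace(values, roi_id="roi"):
    return DffTrace(roi_id=roi_id, values=np.asarray(values, float),
                    frame_rate=RATE, f0=100.0)


def _bump_trace(n, onsets, width=15, amp=1.0):
    v = np.zeros(n)
    for f in onsets:
        v[f:f + width] += amp
    return _trace(v)


class TestEventTriggeredMatrix:
    def test_bump_appears_at_identical_latency(self):
        onsets = np.array([60, 150, 240])
        tr = _bump_trace(400, onsets)
        m = event_triggered_matrix(tr, onsets, "mismatch", pre_s=2.0, post_s=4.0)
        assert m.n_trials == 3
        onset_col = -m.frame_offset
        for row in m.data:
            assert row[onset_col] == 1.0
            assert row[onset_col - 1] == 0.0

    def test_incomplete_window_dropped(self):
        tr = _bump_trace(200, [2, 100, 150])
        m = event_triggered_matrix(tr, np.array([2, 100, 150]), "mismatch",
                                   pre_s=1.0, post_s=2.0)
        assert m.n_trials == 2  # the event at frame 2 cannot host a 1 s pre window

    def test_fewer_than_three_trials_excluded(self):
        tr = _bump_trace(400, [100, 200])
        m = event_triggered_matrix(tr, np.array([100, 200]), "mismatch")
        assert m.n_trials == 2
        assert not m.included


class TestBaselineSubtract:
    def test_constant_row_becomes_zero(self):
        tr = _trace(np.full(400, 0.3))
        m = event_triggered_matrix(tr, np.array([100, 200, 300]), "mismatch")
        b = baseline_subtract(m)
        assert np.allclose(b.data, 0.0)

    def test_locomotion_uses_earlier_window(self):
        assert WINDOW_PROFILES["responsiveness"]["locomotion_onset"][0] == (-1.0, -0.5)
        assert WINDOW_PROFILES["responsiveness"]["grating_onset"][0] == (-0.5, 0.0)

    def test_profile_windows_match_protocol(self):
        prof = WINDOW_PROFILES["responsiveness"]
        assert prof["locomotion_onset"][1] == (0.5, 1.5)
        assert prof["mismatch"][1] == (0.5, 1.5)
        assert prof["grating_onset"][1] == (0.5, 2.5)
        fig2 = WINDOW_PROFILES["fig2_comparison"]
        assert fig2["locomotion_onset"][1] == (0.0, 2.0)
        assert fig2["grating_onset"][1] == (0.5, 3.0)

    def test_linearity_of_baseline_and_window_mean(self, rng):
        vals = rng.normal(0, 0.1, 600)
        onsets = np.array([100, 250, 400])
        c = 3.5
        m1 = baseline_subtract(event_triggered_matrix(_trace(vals), onsets, "mismatch"))
        m2 = baseline_subtract(event_triggered_matrix(_trace(c * vals), onsets, "mismatch"))
        s1 = trial_mean_response(m1)
        s2 = trial_mean_response(m2)
        assert np.allclose(s2, c * s1)


class TestTrialMeanResponse:
    def test_constant_window(self):
        tr = _trace(np.ones(400))
        m = event_triggered_matrix(tr, np.array([100, 200, 300]), "mismatch")
        scalars = trial_mean_response(m)
        assert np.allclose(scalars, 1.0)

    def test_ramp_mean(self):
        # response window 0..2 s over a ramp equal to t gives mean ~1.0
        n = 400
        onset = 200
        v = np.zeros(n)
        ramp_len = int(2 * RATE)
        v[onset:onset + ramp_len] = (np.arange(ramp_len) + 0.5) / RATE
        m = event_triggered_matrix(_trace(v), np.array([60, 130, onset]), "mismatch")
        scalars = trial_mean_response(m, response_window_s=(0.0, 2.0))
        assert scalars[2] == pytest.approx(1.0, abs=1.0 / RATE)


class TestResponsiveness:
    def test_all_zero_not_responsive(self):
        r = responsiveness_ttest(np.zeros(5))
        assert not r.responsive
        assert r.p_value == 1.0

    def test_strong_offset_responsive(self):
        r = responsiveness_ttest(np.array([10.0, 10.1, 9.9, 10.2]))
        assert r.responsive
        assert r.p_value < 1e-6

    def test_zero_variance_nonzero_mean(self):
        r = responsiveness_ttest(np.full(4, 2.0))
        assert r.responsive
        assert r.p_value <= np.finfo(float).tiny

    def test_two_trials_rejected(self):
        with pytest.raises(ValueError):
            responsiveness_ttest(np.array([1.0, 2.0]))


class TestResponsiveFraction:
    def _res(self, flags):
        return [responsiveness_ttest(np.array([10.0, 10.1, 9.9]) if f
                                else np.array([0.1, -0.2, 0.05, 0.0]))
                for f in flags]

    def test_all_responsive(self):
        fr, _, _ = responsive_fraction({"s1": self._res([True] * 4),
                                        "s2": self._res([True] * 3)})
        assert fr == {"s1": 1.0, "s2": 1.0}

    def test_empty_site_omitted(self):
        fr, _, _ = responsive_fraction({"s1": self._res([True, False]), "s2": []})
        assert set(fr) == {"s1"}

    def test_no_sites_error(self):
        with pytest.raises(ValueError):
            responsive_fraction({"s1": []})


class TestChanceInterval:
    def test_noise_band_straddles_zero(self, rng):
        n = 3000
        speed = np.ones(n)
        traces = [_trace(rng.normal(0, 0.05, n), f"r{i}") for i in range(5)]
        t, lo, hi = chance_interval_from_random_triggers(
            traces, speed, n_triggers=10, n_rep=60, seed=0)
        assert np.all(lo <= 0.012)
        assert np.all(hi >= -0.012)
        assert np.mean((lo <= 0) & (hi >= 0)) > 0.9

    def test_constant_traces_zero_width(self):
        n = 2000
        speed = np.ones(n)
        traces = [_trace(np.zeros(n), f"r{i}") for i in range(3)]
        t, lo, hi = chance_interval_from_random_triggers(
            traces, speed, n_triggers=8, n_rep=50, seed=0)
        assert np.allclose(lo, 0.0)
        assert np.allclose(hi, 0.0)

    def test_too_few_repetitions_rejected(self):
        with pytest.raises(ValueError):
            chance_interval_from_random_triggers([_trace(np.zeros(100))],
                                                 np.ones(100), 2, n_rep=10)

    def test_true_response_exceeds_band(self, rng):
        # a deterministic mismatch response pokes above the chance band
        n = 4500
        speed = np.ones(n)
        mismatch_onsets = np.arange(300, 4200, 450)
        amp = 0.2
        traces = []
        for i in range(4):
            v = rng.normal(0, 0.02, n)
            for f in mismatch_onsets:
                v[f:f + 15] += amp
            traces.append(_trace(v, f"r{i}"))
        t, lo, hi = chance_interval_from_random_triggers(
            traces, speed, n_triggers=len(mismatch_onsets), n_rep=60,
            exclude_onsets=mismatch_onsets, seed=0)
        pop = []
        for tr in traces:
            m = baseline_subtract(event_triggered_matrix(tr, mismatch_onsets, "mismatch"))
            pop.append(m.data.mean(axis=0))
        avg = np.mean(pop, axis=0)
        in_window = (t >= 0.0) & (t < 1.0)
        assert np.any(avg[in_window] > hi[in_window])
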