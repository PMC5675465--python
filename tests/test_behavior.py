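"""Sleep drive, PVT sigmoid, bout scoring, and the two-threshold rule."""
import math
from types import SimpleNamespace

import numpy as np
import pytest

from adenosim import (Segment, SleepBout, SystemState,
                      classify_night, daily_sleep_durations, free_run,
                      limit_cycle, merge_bouts, pvt_lapses, regular_day,
                      simulate_protocol, simulate_schedule, sleep_drive,
                      theoretical_max_lapses)
from adenosim.behavior import bouts_in_window
from adenosim.protocol import FREE_SLEEP, build_exp2


class TestSleepDrive:
    def test_no_circadian_modulation(self, full_fit):
        p = full_fit.replace(a=0.0)
        assert sleep_drive(575.0, 13.7, p) == 575.0

    def test_maximal_promotion_at_acrophase(self, full_fit):
        # phi = 7.95 h, a = 3.25 nM
        assert sleep_drive(500.0, 7.95, full_fit) == pytest.approx(
            500.0 + 3.25)

    def test_antiphase(self, full_fit):
        assert sleep_drive(500.0, 7.95 + 12.0, full_fit) == pytest.approx(
            500.0 - 3.25)

    def test_24h_periodic(self, full_fit):
        assert sleep_drive(510.0, 5.0, full_fit) == pytest.approx(
            sleep_drive(510.0, 5.0 + 24.0, full_fit))


class TestPvtLapses:
    def test_half_maximum_at_midpoint(self, full_fit):
        assert pvt_lapses(583.2, full_fit) == pytest.approx(30.0)

    def test_saturation_limits(self, full_fit):
        assert pvt_lapses(-1e6, full_fit) == pytest.approx(0.0, abs=1e-12)
        assert pvt_lapses(1e6, full_fit) == pytest.approx(60.0)

    def test_three_quarter_point(self, full_fit):
        # logistic inversion: P = 0.75 p_max at D_mid + D_s ln 3
        D = full_fit.D_mid + full_fit.D_s * math.log(3.0)
        assert pvt_lapses(D, full_fit) == pytest.approx(45.0)

    def test_monotone_and_bounded(self, full_fit):
        D = np.linspace(520.0, 650.0, 200)
        P = pvt_lapses(D, full_fit)
        assert np.all(np.diff(P) > 0)
        assert np.all((P > 0) & (P < full_fit.p_max))
        # far tails stay inside [0, p_max]
        tails = pvt_lapses(np.array([0.0, 2000.0]), full_fit)
        assert tails[0] >= 0.0 and tails[1] <= full_fit.p_max

    def test_invalid_width(self):
        bad = SimpleNamespace(D_mid=580.0, D_s=0.0, p_max=60.0)
        with pytest.raises(ValueError):
            pvt_lapses(580.0, bad)


class TestTheoreticalMaxLapses:
    @pytest.mark.parametrize("delta,expected", [
        (0.5, 92),   # responding exactly at the lapse boundary
        (4.0, 60),   # severe-impairment response times
        (0.0, 100),
    ])
    def test_ceilings(self, delta, expected):
        assert theoretical_max_lapses(delta) == expected

    def test_negative_delta(self):
        with pytest.raises(ValueError):
            theoretical_max_lapses(-0.1)


class TestBoutScoring:
    def test_classification_counts(self):
        b = lambda o, f: SleepBout(o, f)
        assert classify_night([]) == "none"
        assert classify_night([b(22, 30)]) == "monophasic"
        assert classify_night([b(19, 23), b(26, 30)]) == "biphasic"
        assert classify_night([b(19, 20), b(21, 22), b(23, 24)]) == \
            "polyphasic"

    def test_momentary_arousal_merged(self):
        # two bouts separated by 2 minutes count as one episode
        bouts = [SleepBout(22.0, 25.0), SleepBout(25.0 + 2 / 60, 30.0)]
        assert classify_night(bouts) == "monophasic"
        merged = merge_bouts(bouts)
        assert len(merged) == 1
        assert merged[0].onset == 22.0
        assert merged[0].offset == 30.0

    def test_gap_at_threshold_not_merged(self):
        bouts = [SleepBout(22.0, 25.0), SleepBout(25.0 + 6 / 60, 30.0)]
        assert len(merge_bouts(bouts)) == 2


class TestDailySleepDurations:
    def test_single_night_bout(self):
        out = daily_sleep_durations([SleepBout(22.0, 30.0)])
        assert out == [(1, 8.0)]

    def test_split_night_sums_to_one_day(self):
        out = daily_sleep_durations(
            [SleepBout(19.0, 23.0), SleepBout(26.0, 30.0)], n_days=1)
        assert out == [(1, pytest.approx(8.0))]

    def test_no_bouts(self):
        assert daily_sleep_durations([], n_days=2) == [(1, 0.0), (2, 0.0)]

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError):
            daily_sleep_durations(
                [SleepBout(20.0, 24.0), SleepBout(23.0, 26.0)])

    def test_clipping_to_window(self):
        # sleep extending past 08:00 is not scored into the night window
        out = daily_sleep_durations([SleepBout(30.0, 34.0)], n_days=1)
        assert out == [(1, pytest.approx(2.0))]


class TestFreeRun:
    def test_unreachable_threshold_gives_pure_wake(self, full_fit):
        p = full_fit.replace(D_sleep=1e4)
        state = SystemState(0.0, 700.0, 600.0, "wake")
        states, bouts = free_run(state, Segment(0.0, 14.0, FREE_SLEEP), p,
                                 dt=0.02)
        assert bouts == []
        assert all(s.vigilance == "wake" for s in states)
        assert states[-1].t == pytest.approx(14.0)

    def test_rejects_forced_window(self, full_fit):
        state = SystemState(0.0, 700.0, 600.0, "wake")
        with pytest.raises(ValueError):
            free_run(state, Segment(0.0, 14.0, "forced_wake"), full_fit)

    def test_hysteresis_at_transitions(self, full_fit):
        """Sleep onsets sit at D_sleep, spontaneous wake onsets at D_wake."""
        proto = build_exp2(n_days=4)
        traj = simulate_protocol(proto, full_fit, dt=0.02)
        D = traj.D
        eps = 1e-3
        free_windows = [(s.start, s.end)
                        for s in proto.schedule.free_windows()]
        for b in traj.bouts:
            in_free = any(w0 - 1e-9 <= b.onset <= w1 + 1e-9
                          for (w0, w1) in free_windows)
            if not in_free:
                continue
            i = int(np.argmin(np.abs(traj.t - b.onset)))
            assert D[i] >= full_fit.D_sleep - eps
            # offsets at a window edge are forced, not spontaneous
            if not any(abs(b.offset - w1) < 1e-6 for (_, w1) in free_windows):
                j = int(np.argmin(np.abs(traj.t - b.offset)))
                assert D[j] <= full_fit.D_wake + eps

    def test_no_threshold_overshoot_at_sleep_onset(self, full_fit):
        """At each spontaneous sleep onset the drive sits at the threshold
        and falls over the following step: no overshoot beyond one
        integration step.  (Later in the night the drive may legitimately
        re-exceed the sleep threshold through the circadian rise — the
        hysteretic rule keeps the model asleep until the wake threshold.)"""
        proto = build_exp2(n_days=3)
        traj = simulate_protocol(proto, full_fit, dt=0.02)
        D = traj.D
        onsets = np.flatnonzero(traj.awake[:-1] & ~traj.awake[1:])
        assert onsets.size > 0
        for i in onsets:
            clock = traj.t[i] % 24.0
            if min(abs(clock - 8.0), abs(clock - 18.0)) < 1e-6:
                continue  # forced boundary, not a spontaneous crossing
            assert D[i] <= full_fit.D_sleep + 1e-3
            if i + 2 < D.size and not traj.awake[i + 2]:
                assert D[i + 2] <= D[i] + 1e-3  # falling after onset


class TestPerformanceWithinDay:
    def test_evening_decline_in_performance(self, full_fit):
        """Predicted lapses rise through the final hours of a habitual
        16 h waking day (circadian alertness peak passed while
        homeostatic pressure continues to build)."""
        lc = limit_cycle(regular_day(8.0), full_fit)
        traj = simulate_schedule(regular_day(8.0), full_fit,
                                 SystemState(0.0, lc.A_tot, lc.R1_tot,
                                             lc.vigilance), dt=0.01)
        sel = (traj.t >= 18.0) & (traj.t <= 24.0)
        P = traj.P[sel]
        assert np.all(np.diff(P) > 0)


def test_bouts_in_window_clipping():
    bouts = [SleepBout(10.0, 20.0), SleepBout(25.0, 30.0)]
    out = bouts_in_window(bouts, 18.0, 26.0)
    assert [(b.onset, b.offset) for b in out] == [(18.0, 20.0),
                                                  (25.0, 26.0)]
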