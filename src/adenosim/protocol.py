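"""Machine-readable sleep/wake schedules and the two experiment presets.

Time is absolute hours from schedule start; clock time is ``t mod 24``
with 0 = midnight.  A schedule is an ordered, contiguous list of segments,
each ``forced_wake``, ``forced_sleep``, or ``free_sleep`` (a window in
which the model chooses its own sleep/wake transitions via the
two-threshold rule).

Experiment presets:

* Experiment 1 — forced schedules for PVT calibration: 88 h acute sleep
  deprivation, or 13 nights of restricted sleep (achieved sleep 3.7 h or
  5.5 h per night for the 4 h and 6 h time-in-bed groups) followed by two
  7.0 h recovery nights, or 15 nights of 6.8 h (8 h time-in-bed group).
  All groups share three 7.0 h baseline nights and a pre-study history of
  7.8 h sleep per night; every sleep episode ends at 08:00.
* Experiment 2 — long-night recovery: after a history of 7 h sleep per
  night beginning at midnight, 50 days of forced wake 08:00-18:00 with a
  free 14 h sleep opportunity 18:00-08:00 each night.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .errors import ConfigError

__all__ = [
    "FORCED_WAKE",
    "FORCED_SLEEP",
    "FREE_SLEEP",
    "Segment",
    "Schedule",
    "ProtocolSpec",
    "regular_day",
    "build_exp1",
    "build_exp2",
    "pvt_sample_times",
    "EXP1_CONDITIONS",
    "PROTOCOL_PRESETS",
]

FORCED_WAKE = "forced_wake"
FORCED_SLEEP = "forced_sleep"
FREE_SLEEP = "free_sleep"
_MODES = (FORCED_WAKE, FORCED_SLEEP, FREE_SLEEP)

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"unknown segment mode {self.mode!r}")
        if not self.end > self.start:
            raise ConfigError(
                f"segment must have start < end, got [{self.start}, {self.end}]"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Schedule:
    """Ordered, contiguous, non-overlapping segments."""

    segments: Tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ConfigError("schedule must contain at least one segment")
        for prev, cur in zip(segs, segs[1:]):
            if abs(cur.start - prev.end) > _EPS:
                raise ConfigError(
                    f"segments must be contiguous: [{prev.start}, {prev.end}] "
                    f"then [{cur.start}, {cur.end}]"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    def wake_intervals(self) -> List[Tuple[float, float]]:
        """Maximal intervals of forced wakefulness (merging adjacent ones)."""
        out: List[Tuple[float, float]] = []
        for seg in self.segments:
            if seg.mode != FORCED_WAKE:
                continue
            if out and abs(out[-1][1] - seg.start) <= _EPS:
                out[-1] = (out[-1][0], seg.end)
            else:
                out.append((seg.start, seg.end))
        return out

    def sleep_segments(self) -> List[Segment]:
        return [s for s in self.segments if s.mode == FORCED_SLEEP]

    def free_windows(self) -> List[Segment]:
        return [s for s in self.segments if s.mode == FREE_SLEEP]

    def mode_at(self, t: float) -> str:
        for seg in self.segments:
            if seg.start - _EPS <= t < seg.end - _EPS:
                return seg.mode
        if abs(t - self.end) <= _EPS:
            return self.segments[-1].mode
        raise ConfigError(f"time {t} outside schedule [{self.start}, {self.end}]")

    def to_records(self) -> List[dict]:
        return [
            {"start": s.start, "end": s.end, "mode": s.mode}
            for s in self.segments
        ]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "Schedule":
        try:
            segs = tuple(
                Segment(float(r["start"]), float(r["end"]), str(r["mode"]))
                for r in records
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed schedule records: {exc}") from exc
        return cls(segs)


@dataclass(frozen=True)
class ProtocolSpec:
    """A schedule plus its initialization recipe.

    ``init_day`` is a repeating 24 h forced schedule whose limit cycle
    provides the initial state; its day boundary (t = 0, midnight) must be
    vigilance-continuous with the start of ``schedule``.
    ``t_condition_start`` marks where the experimental condition begins
    (time 0 of the published protocols' x-axes is the preceding midnight).
    """

    name: str
    schedule: Schedule
    init_day: Schedule
    t_condition_start: float = 0.0

    def night_windows(self, anchor: float = 18.0, length: float = 14.0,
                      ) -> List[Tuple[float, float]]:
        """Nightly scoring windows [anchor + 24k, anchor + 24k + length)."""
        out = []
        t = self.t_condition_start
        # first anchor at/after condition start
        k0 = math.ceil((t - anchor) / 24.0 - _EPS)
        w = anchor + 24.0 * k0
        while w < self.schedule.end - _EPS:
            out.append((w, min(w + length, self.schedule.end)))
            w += 24.0
        return out


def regular_day(sleep_hours: float, wake_time: float = 8.0) -> Schedule:
    """A 24 h day with one sleep block ending at ``wake_time``.

    The day spans [0, 24) with 0 = midnight; a sleep block that would
    begin before midnight wraps around.
    """
    if not 0.0 < sleep_hours < 24.0:
        raise ConfigError("sleep_hours must be in (0, 24)")
    onset = (wake_time - sleep_hours) % 24.0
    segs: List[Segment] = []
    if onset < wake_time:
        if onset > 0.0:
            segs.append(Segment(0.0, onset, FORCED_WAKE))
        segs.append(Segment(onset, wake_time, FORCED_SLEEP))
        if wake_time < 24.0:
            segs.append(Segment(wake_time, 24.0, FORCED_WAKE))
    else:  # wraps past midnight
        segs.append(Segment(0.0, wake_time, FORCED_SLEEP))
        segs.append(Segment(wake_time, onset, FORCED_WAKE))
        segs.append(Segment(onset, 24.0, FORCED_SLEEP))
    return Schedule(tuple(segs))


#: Experiment 1 condition labels -> (restricted nights, recovery nights).
EXP1_CONDITIONS = {
    "deprivation_88h": ([], 0),
    "tib4": ([3.7] * 13, 2),
    "tib6": ([5.5] * 13, 2),
    "tib8": ([6.8] * 15, 0),
}

_BASELINE_NIGHTS = 3
_BASELINE_SLEEP = 7.0
_RECOVERY_SLEEP = 7.0
_PRESTUDY_SLEEP = 7.8
_WAKE_TIME = 8.0  # all awakenings anchored at 08:00
_DEPRIVATION_HOURS = 88.0


def _nightly_schedule(night_sleeps: Sequence[float], tail_hours: float,
                      ) -> Schedule:
    """Forced schedule from a list of per-night sleep durations.

    Night i (1-based) ends at 08:00 of day i, i.e. t = 24*(i-1) + 8; each
    night's sleep episode is anchored to end at 08:00.  ``tail_hours`` of
    wake are appended after the final awakening.
    """
    segs: List[Segment] = []
    t = 0.0
    for i, T in enumerate(night_sleeps, start=1):
        wake_at = 24.0 * (i - 1) + _WAKE_TIME
        onset = wake_at - T
        if onset < t - _EPS:
            raise ConfigError(
                f"night {i} sleep of {T} h would start before previous wake"
            )
        if onset > t + _EPS:
            segs.append(Segment(t, onset, FORCED_WAKE))
        segs.append(Segment(onset, wake_at, FORCED_SLEEP))
        t = wake_at
    if tail_hours > 0.0:
        segs.append(Segment(t, t + tail_hours, FORCED_WAKE))
    return Schedule(tuple(segs))


def build_exp1(condition: str) -> ProtocolSpec:
    """Forced schedule + initialization recipe for an Experiment-1 condition.

    Initialization: limit cycle on a 7.8 h-sleep day (pre-study habitual
    sleep).  The schedule then runs 3 baseline nights of 7.0 h, the
    condition nights, and (for the restriction conditions with recovery)
    2 recovery nights of 7.0 h, all sleep episodes ending at 08:00.  For
    the deprivation condition, 88 h of continuous wake follow the 08:00
    awakening after baseline.
    """
    if condition not in EXP1_CONDITIONS:
        raise ConfigError(
            f"unknown condition {condition!r}; "
            f"choose from {sorted(EXP1_CONDITIONS)}"
        )
    nights, n_recovery = EXP1_CONDITIONS[condition]
    all_nights = [_BASELINE_SLEEP] * _BASELINE_NIGHTS + list(nights) \
        + [_RECOVERY_SLEEP] * n_recovery
    t_condition = 24.0 * (_BASELINE_NIGHTS - 1) + _WAKE_TIME  # 08:00 after baseline
    if condition == "deprivation_88h":
        sched = _nightly_schedule(all_nights, tail_hours=_DEPRIVATION_HOURS)
    else:
        # wake until midnight after the final awakening
        sched = _nightly_schedule(all_nights, tail_hours=24.0 - _WAKE_TIME)
    init_day = regular_day(_PRESTUDY_SLEEP, wake_time=_WAKE_TIME)
    return ProtocolSpec(name=f"exp1:{condition}", schedule=sched,
                        init_day=init_day, t_condition_start=t_condition)


def build_exp2(n_days: int = 50) -> ProtocolSpec:
    """Long-night protocol: forced wake 08:00-18:00, free sleep 18:00-08:00.

    Initialization: limit cycle on a 7 h-sleep day with sleep beginning at
    midnight.  The schedule starts at midnight with the final 7 h forced
    sleep of the habituation history, then ``n_days`` free nights.
    """
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    segs: List[Segment] = [
        Segment(0.0, 7.0, FORCED_SLEEP),
        Segment(7.0, 18.0, FORCED_WAKE),
    ]
    t = 18.0
    for k in range(n_days):
        segs.append(Segment(t, t + 14.0, FREE_SLEEP))
        t += 14.0
        if k < n_days - 1:
            segs.append(Segment(t, t + 10.0, FORCED_WAKE))
            t += 10.0
    sched = Schedule(tuple(segs))
    init_day = regular_day(7.0, wake_time=7.0)
    return ProtocolSpec(name="exp2", schedule=sched, init_day=init_day,
                        t_condition_start=0.0)


def pvt_sample_times(schedule: Schedule, start: float | None = None,
                     first_offset: float = 4.0, interval: float = 2.0,
                     ) -> np.ndarray:
    """PVT sampling grid: every 2 h during wakefulness, from wake + 4 h.

    The first test of each wake period falls 4 h after awakening (sleep
    inertia exclusion); sampling stops at the last gridpoint strictly
    before the next sleep onset (or schedule end).  With ``start`` given,
    only samples at or after that time are returned.
    """
    times: List[float] = []
    for (w0, w1) in schedule.wake_intervals():
        t = w0 + first_offset
        while t < w1 - _EPS:
            times.append(t)
            t += interval
    out = np.asarray(times, dtype=float)
    if start is not None:
        out = out[out >= start - _EPS]
    return out


def _protocol_preset(name: str) -> ProtocolSpec:
    if name == "exp2":
        return build_exp2()
    if name.startswith("exp1:"):
        return build_exp1(name.split(":", 1)[1])
    raise ConfigError(
        f"unknown protocol preset {name!r}; choose from {PROTOCOL_PRESETS}"
    )


PROTOCOL_PRESETS = ["exp2"] + [f"exp1:{c}" for c in EXP1_CONDITIONS]
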