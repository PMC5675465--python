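"""Sleep drive, PVT lapses, and autonomous sleep/wake switching.

The sleep homeostatic process is identified with the bound A1 receptor
concentration ``R1_b``; adding a fixed 24 h sinusoid gives the overall
sleep drive ``D = R1_b + a cos(omega (t - phi))``.  A bounded sigmoid maps
``D`` to predicted lapses on the 10-minute psychomotor vigilance test.

During free-sleep windows the model picks its own sleep/wake transitions
with a hysteretic two-threshold rule: transition to sleep when ``D``
rises through ``D_sleep`` while awake, transition to wake when ``D``
falls through ``D_wake`` while asleep; between the thresholds the current
vigilance persists.  Transition times are refined by bisection within the
integration step that brackets the crossing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.special import expit

from . import _kernels as _k
from .core import DEFAULT_DT, SLEEP, WAKE, SystemState, _a1b_root
from .params import OMEGA, ModelParameters
from .protocol import FREE_SLEEP, Segment

__all__ = [
    "SleepBout",
    "PVTObservation",
    "sleep_drive",
    "pvt_lapses",
    "theoretical_max_lapses",
    "free_run",
    "merge_bouts",
    "classify_night",
    "daily_sleep_durations",
    "bouts_in_window",
]

#: Bisection tolerance on transition times (h).
TRANSITION_TOL = _k.TRANSITION_TOL

#: Bouts separated by less than this gap (h) are merged before scoring
#: (momentary arousals are not counted as separate episodes).
MERGE_GAP = 5.0 / 60.0


@dataclass(frozen=True)
class SleepBout:
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("bout must have offset > onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class PVTObservation:
    """A lapse count at an absolute time (fractional for group means)."""

    t: float
    lapses: float


def sleep_drive(R1_b, t, params: ModelParameters):
    """Overall sleep drive: homeostatic R1_b plus the circadian sinusoid.

    Maximal circadian sleep promotion occurs at clock time ``phi``
    (early morning, near the core body temperature minimum).
    Vectorized over both arguments.
    """
    return R1_b + params.a * np.cos(OMEGA * (np.asarray(t) - params.phi))


def pvt_lapses(D, params: ModelParameters):
    """Predicted PVT lapse count from the sleep drive.

    Logistic in ``D``: half-maximal at ``D_mid``, width ``D_s``, saturating
    at ``p_max``.  Strictly increasing and bounded in (0, p_max).
    """
    if params.D_s <= 0.0:
        raise ValueError("D_s must be > 0")
    out = params.p_max * expit((np.asarray(D) - params.D_mid) / params.D_s)
    return float(out) if np.ndim(D) == 0 else out


def theoretical_max_lapses(delta: float, test_duration: float = 600.0,
                           mean_iti: float = 6.0) -> int:
    """Lapse ceiling for a response time of ``delta`` seconds per trial.

    Trials arrive every ``mean_iti + delta`` seconds on average, so at
    most ``floor(test_duration / (mean_iti + delta))`` trials (all lapsed)
    fit in one test.  At the 500 ms lapse boundary this gives 92; at the
    ~4 s response times seen under severe sleep loss, 60.
    """
    if delta < 0.0:
        raise ValueError("delta must be >= 0")
    if test_duration <= 0.0 or mean_iti <= 0.0:
        raise ValueError("durations must be > 0")
    return int(math.floor(test_duration / (mean_iti + delta)))


def _drive_scalar(A: float, R: float, t: float, p: ModelParameters,
                  K: float) -> float:
    return _a1b_root(A, R, K) + p.a * math.cos(OMEGA * (t - p.phi))


def _free_window_arrays(t: float, A: float, R: float, awake: bool,
                        window: Segment, params: ModelParameters,
                        dt: float):
    """Run the free-window kernel; returns trimmed record and bout arrays.

    The recorded arrays hold every step endpoint and every transition
    point (the entry state is excluded); returns
    ``(ts, As, Rs, awakes, onsets, offsets, A_end, R_end, awake_end)``.
    """
    p = params
    K = p.Kd1 / (1.0 - p.beta)
    n_steps = int((window.end - t) / dt) + 2
    cap = 2 * n_steps + 4
    out_t = np.empty(cap)
    out_A = np.empty(cap)
    out_R = np.empty(cap)
    out_awake = np.empty(cap, dtype=np.bool_)
    out_on = np.empty(n_steps + 2)
    out_off = np.empty(n_steps + 2)
    m, nb, A_end, R_end, awake_end = _k.free_window(
        t, A, R, awake, window.end, dt,
        p.mu_wake, p.chi_wake, p.mu_sleep, p.chi_sleep, K, p.gamma,
        p.lambda_, p.a, p.phi, OMEGA, p.D_sleep, p.D_wake,
        out_t, out_A, out_R, out_awake, out_on, out_off)
    return (out_t[:m], out_A[:m], out_R[:m], out_awake[:m],
            out_on[:nb], out_off[:nb], A_end, R_end, bool(awake_end))


def free_run(state: SystemState, window: Segment, params: ModelParameters,
             dt: float = DEFAULT_DT,
             ) -> Tuple[List[SystemState], List[SleepBout]]:
    """Advance through a free-sleep window applying the hysteretic rule.

    Transition to sleep when the drive rises through ``D_sleep`` while
    awake; to wake when it falls through ``D_wake`` while asleep; between
    the thresholds the current vigilance persists.  Crossing times are
    refined by bisection within the bracketing integration step.

    Returns the recorded states (including the entry state and every
    transition point) and the sleep bouts found in the window.  A bout
    still open at the window's end is truncated there (the next segment
    forces wakefulness).  Zero or many bouts per window are all legal.
    """
    if window.mode != FREE_SLEEP:
        raise ValueError("free_run requires a free-sleep window")
    if not abs(state.t - window.start) < 1e-9:
        raise ValueError("state must be at the window start")
    ts, As, Rs, awakes, ons, offs, *_ = _free_window_arrays(
        state.t, state.A_tot, state.R1_tot, state.vigilance == WAKE,
        window, params, dt)
    states = [state]
    states.extend(
        SystemState(float(t), float(a), float(r), WAKE if w else SLEEP)
        for t, a, r, w in zip(ts, As, Rs, awakes)
    )
    bouts = [SleepBout(float(o), float(f)) for o, f in zip(ons, offs)]
    return states, bouts


def merge_bouts(bouts: Sequence[SleepBout],
                gap: float = MERGE_GAP) -> List[SleepBout]:
    """Merge bouts separated by less than ``gap`` hours."""
    if not bouts:
        return []
    ordered = sorted(bouts, key=lambda b: b.onset)
    out = [ordered[0]]
    for b in ordered[1:]:
        if b.onset - out[-1].offset < gap:
            out[-1] = SleepBout(out[-1].onset, max(out[-1].offset, b.offset))
        else:
            out.append(b)
    return out


def classify_night(bouts: Sequence[SleepBout], gap: float = MERGE_GAP) -> str:
    """Count-based classification of one night window's sleep pattern.

    Bouts separated by less than ``gap`` are merged first, so momentary
    arousals do not inflate the count.  Returns one of ``'none'``,
    ``'monophasic'``, ``'biphasic'``, ``'polyphasic'``.
    """
    n = len(merge_bouts(bouts, gap=gap))
    if n == 0:
        return "none"
    if n == 1:
        return "monophasic"
    if n == 2:
        return "biphasic"
    return "polyphasic"


def bouts_in_window(bouts: Sequence[SleepBout], start: float, end: float,
                    ) -> List[SleepBout]:
    """Bouts clipped to [start, end), dropping empty intersections.

    Bouts must already be ordered (as produced by the simulator).
    """
    out = []
    for b in bouts:
        if b.onset >= end:
            break
        lo, hi = max(b.onset, start), min(b.offset, end)
        if hi > lo:
            out.append(SleepBout(lo, hi))
    return out


def daily_sleep_durations(bouts: Sequence[SleepBout],
                          n_days: int | None = None,
                          night_anchor: float = 18.0,
                          window_hours: float = 14.0,
                          ) -> List[Tuple[int, float]]:
    """Total sleep per nightly window, as (day index, hours) pairs.

    Night ``n`` (1-based) is the window ``[night_anchor + 24 (n-1),
    night_anchor + 24 (n-1) + window_hours)``; sleep inside it is assigned
    to day ``n``.  With ``n_days`` given, exactly that many rows are
    returned (zeros where no sleep occurred); otherwise nights are
    enumerated to cover every bout.
    """
    for prev, cur in zip(bouts, list(bouts)[1:]):
        if cur.onset < prev.offset - 1e-9:
            raise ValueError("bouts must be ordered and disjoint")
    if n_days is None:
        if not bouts:
            return []
        last = max(b.offset for b in bouts)
        n_days = max(1, int(math.ceil((last - night_anchor) / 24.0)))
    out: List[Tuple[int, float]] = []
    for n in range(1, n_days + 1):
        w0 = night_anchor + 24.0 * (n - 1)
        w1 = w0 + window_hours
        total = sum(b.duration for b in bouts_in_window(bouts, w0, w1))
        out.append((n, total))
    return out
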