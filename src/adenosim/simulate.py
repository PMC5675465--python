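"""Whole-protocol simulation: forced segments, free windows, trajectories."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analytics import limit_cycle
from .behavior import (SleepBout, _free_window_arrays, pvt_lapses,
                       sleep_drive)
from .core import (DEFAULT_DT, SLEEP, WAKE, SystemState, _advance,
                   _advance_arrays, binding_equilibrium)
from .errors import ConfigError
from .params import ModelParameters
from .protocol import (FORCED_WAKE, FREE_SLEEP, ProtocolSpec, Schedule)

__all__ = ["Trajectory", "simulate_schedule", "simulate_protocol",
           "run_schedule_bouts", "states_at_times"]


@dataclass
class Trajectory:
    """Time-gridded record of a simulation.

    Points are ordered in time but not uniformly spaced: every integration
    step is recorded, plus every detected sleep/wake transition.  Bound
    and unbound pools, sleep drive, and predicted PVT lapses are derived
    lazily from the slow state.
    """

    t: np.ndarray
    A_tot: np.ndarray
    R1_tot: np.ndarray
    awake: np.ndarray
    bouts: List[SleepBout]
    params: ModelParameters
    schedule: Optional[Schedule] = None
    _pools: object = field(default=None, repr=False)

    @property
    def pools(self):
        if self._pools is None:
            self._pools = binding_equilibrium(self.A_tot, self.R1_tot,
                                              self.params)
        return self._pools

    @property
    def R1_b(self) -> np.ndarray:
        return self.pools.R1_b

    @property
    def A_u(self) -> np.ndarray:
        return self.pools.A_u

    @property
    def D(self) -> np.ndarray:
        return sleep_drive(self.R1_b, self.t, self.params)

    @property
    def P(self) -> np.ndarray:
        return pvt_lapses(self.D, self.params)

    def final_state(self) -> SystemState:
        vig = WAKE if self.awake[-1] else SLEEP
        return SystemState(float(self.t[-1]), float(self.A_tot[-1]),
                           float(self.R1_tot[-1]), vig)

    def to_frame(self) -> pd.DataFrame:
        pools = self.pools
        return pd.DataFrame({
            "t": self.t,
            "A_tot": self.A_tot,
            "A_u": pools.A_u,
            "A1_b": pools.A1_b,
            "A2_b": pools.A2_b,
            "R1_tot": self.R1_tot,
            "R1_b": pools.R1_b,
            "D": self.D,
            "P": self.P,
            "vigilance": np.where(self.awake, WAKE, SLEEP),
        })

    def bouts_frame(self) -> pd.DataFrame:
        rows = [{
            "onset": b.onset,
            "offset": b.offset,
            "duration": b.duration,
            "day": int(np.floor(b.onset / 24.0)) + 1,
        } for b in self.bouts]
        return pd.DataFrame(rows,
                            columns=["onset", "offset", "duration", "day"])


def simulate_schedule(schedule: Schedule, params: ModelParameters,
                      initial: SystemState, dt: float = DEFAULT_DT,
                      ) -> Trajectory:
    """Integrate a full schedule from the given initial state.

    Forced segments impose vigilance; free-sleep windows run the
    two-threshold rule.  ``A_tot`` is continuous everywhere; vigilance
    switches discontinuously at segment boundaries and detected
    transitions.
    """
    if abs(initial.t - schedule.start) > 1e-9:
        raise ConfigError("initial state must be at the schedule start")
    t, A, R = initial.t, initial.A_tot, initial.R1_tot
    vig = initial.vigilance
    ts = [np.array([t])]
    As = [np.array([A])]
    Rs = [np.array([R])]
    aw = [np.array([vig == WAKE])]
    bouts: List[SleepBout] = []
    for seg in schedule.segments:
        if seg.mode == FREE_SLEEP:
            (st, sA, sR, sw, ons, offs, A, R, awake_end
             ) = _free_window_arrays(t, A, R, vig == WAKE, seg, params, dt)
            ts.append(st)
            As.append(sA)
            Rs.append(sR)
            aw.append(sw)
            bouts.extend(SleepBout(float(o), float(f))
                         for o, f in zip(ons, offs))
            t = seg.end
            vig = WAKE if awake_end else SLEEP
            continue
        mode = WAKE if seg.mode == FORCED_WAKE else SLEEP
        if vig != mode:
            # vigilance is imposed by the segment; record the switch
            vig = mode
            ts.append(np.array([t]))
            As.append(np.array([A]))
            Rs.append(np.array([R]))
            aw.append(np.array([vig == WAKE]))
        st, sA, sR, A, R = _advance_arrays(t, A, R, mode, seg.duration,
                                           params, dt)
        t = seg.end
        ts.append(st)
        As.append(sA)
        Rs.append(sR)
        aw.append(np.full(st.size, mode == WAKE))
        if mode == SLEEP:
            bouts.append(SleepBout(seg.start, seg.end))
    return Trajectory(
        t=np.concatenate(ts), A_tot=np.concatenate(As),
        R1_tot=np.concatenate(Rs),
        awake=np.concatenate(aw).astype(bool), bouts=bouts, params=params,
        schedule=schedule,
    )


def run_schedule_bouts(schedule: Schedule, params: ModelParameters,
                       initial: SystemState, dt: float = DEFAULT_DT,
                       ) -> Tuple[SystemState, List[SleepBout]]:
    """Fast path: integrate a schedule returning only the final state and
    the sleep bouts (no trajectory recording)."""
    if abs(initial.t - schedule.start) > 1e-9:
        raise ConfigError("initial state must be at the schedule start")
    t, A, R = initial.t, initial.A_tot, initial.R1_tot
    vig = initial.vigilance
    bouts: List[SleepBout] = []
    for seg in schedule.segments:
        if seg.mode == FREE_SLEEP:
            (_, _, _, _, ons, offs, A, R, awake_end
             ) = _free_window_arrays(t, A, R, vig == WAKE, seg, params, dt)
            bouts.extend(SleepBout(float(o), float(f))
                         for o, f in zip(ons, offs))
            t = seg.end
            vig = WAKE if awake_end else SLEEP
            continue
        mode = WAKE if seg.mode == FORCED_WAKE else SLEEP
        vig = mode
        t, A, R = _advance(t, A, R, mode, seg.duration, params, dt)
        if mode == SLEEP:
            bouts.append(SleepBout(seg.start, seg.end))
    return SystemState(t, A, R, vig), bouts


def simulate_protocol(proto: ProtocolSpec, params: ModelParameters,
                      dt: float = DEFAULT_DT,
                      lc_tol: float = 1e-8) -> Trajectory:
    """Limit-cycle initialization followed by the protocol schedule."""
    init = limit_cycle(proto.init_day, params, tol=lc_tol, dt=dt)
    start = SystemState(proto.schedule.start, init.A_tot, init.R1_tot,
                        init.vigilance)
    return simulate_schedule(proto.schedule, params, start, dt=dt)


def states_at_times(schedule: Schedule, params: ModelParameters,
                    times: Sequence[float], initial: SystemState,
                    dt: float = DEFAULT_DT,
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """(A_tot, R1_tot) sampled at the given times along a forced schedule.

    Integration is split exactly at each requested time, so samples are
    evaluated at the stated instants rather than interpolated.  Times
    inside free-sleep windows are not supported (PVT testing happens
    during scheduled wakefulness).
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0)):
        raise ConfigError("sample times must be sorted ascending")
    if times.size and (times[0] < schedule.start - 1e-9
                       or times[-1] > schedule.end + 1e-9):
        raise ConfigError("sample times outside the schedule span")
    t, A, R = initial.t, initial.A_tot, initial.R1_tot
    vig = initial.vigilance
    A_out = np.empty_like(times)
    R_out = np.empty_like(times)
    idx = 0
    for seg in schedule.segments:
        if seg.mode == FREE_SLEEP:
            if idx < times.size and times[idx] < seg.end - 1e-9:
                raise ConfigError(
                    "sample times inside free-sleep windows are not supported"
                )
            (_, _, _, _, _, _, A, R, awake_end
             ) = _free_window_arrays(t, A, R, vig == WAKE, seg, params, dt)
            t = seg.end
            vig = WAKE if awake_end else SLEEP
            continue
        mode = WAKE if seg.mode == FORCED_WAKE else SLEEP
        vig = mode
        while idx < times.size and times[idx] < seg.end - 1e-9:
            t, A, R = _advance(t, A, R, mode, max(times[idx] - t, 0.0),
                               params, dt)
            A_out[idx] = A
            R_out[idx] = R
            idx += 1
        t, A, R = _advance(t, A, R, mode, seg.end - t, params, dt)
    if idx < times.size:
        raise ConfigError("sample times extend beyond the schedule")
    return A_out, R_out
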