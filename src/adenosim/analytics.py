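"""Closed-form steady-state and periodic-boundary relations.

These identities serve parameter estimation and initialization:

* the homeostatic target occupancy implied by the mean unbound adenosine
  level, ``gamma = <A_u> / (<A_u> + Kd1)``;
* the algebraic map between total and unbound adenosine at the
  quasistatic binding equilibrium, and its inverse;
* the fixed point of the alternating wake/sleep exponential relaxations
  on a regular 24 h schedule (periodic boundary values of ``A_tot``), and
  the coefficients expressing the resulting typical concentration as a
  linear combination of ``mu_wake`` and ``mu_sleep``;
* numerical limit-cycle initialization for arbitrary repeating 24 h
  forced schedules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from .core import (DEFAULT_DT, SLEEP, WAKE, SystemState, _a1b_root,
                   _advance)
from .errors import ConfigError, ConvergenceError
from .params import ModelParameters
from .protocol import FORCED_SLEEP, FORCED_WAKE, Schedule

__all__ = [
    "PeriodicBoundary",
    "gamma_target",
    "au_from_atot",
    "atot_from_au",
    "typical_atot_coefficients",
    "periodic_initials",
    "equilibrium_receptor_total",
    "limit_cycle",
]


@dataclass(frozen=True)
class PeriodicBoundary:
    """Periodic boundary values of A_tot on a regular 24 h schedule.

    ``T`` is the daily sleep duration; ``A_sleep0`` and ``A_wake0`` are
    the total adenosine concentrations at sleep onset and wake onset.
    For ``0 < T < 24`` they satisfy
    ``mu_sleep < A_wake0 < A_sleep0 < mu_wake``.
    """

    T: float
    A_sleep0: float
    A_wake0: float

    @property
    def mean(self) -> float:
        """Plain average of the two boundary values (typical A_tot)."""
        return 0.5 * (self.A_sleep0 + self.A_wake0)


def gamma_target(Au_mean: float, Kd1: float) -> float:
    """Target occupancy fraction from the steady-state occupancy relation.

    At the periodic steady state the receptor pool settles where the mean
    occupancy equals ``gamma``; to leading order this gives
    ``gamma = <A_u> / (<A_u> + Kd1)``.
    """
    if Kd1 <= 0.0:
        raise ValueError(f"Kd1 must be > 0, got {Kd1!r}")
    if Au_mean < 0.0:
        raise ValueError(f"Au_mean must be >= 0, got {Au_mean!r}")
    return Au_mean / (Au_mean + Kd1)


def au_from_atot(A_tot: float, R1_tot: float, Kd1: float, beta: float) -> float:
    """Unbound adenosine from the total pool at binding equilibrium.

    Evaluates ``2 A_u = (1-beta) (A_tot - R1_tot - K + sqrt((A_tot + R1_tot
    + K)^2 - 4 A_tot R1_tot))`` with ``K = Kd1/(1-beta)``, rearranged to
    avoid cancellation when ``A_tot < R1_tot + K``.  This is a route
    independent of the quadratic-root solver used by the integrator.
    """
    if A_tot < 0.0 or R1_tot <= 0.0 or Kd1 <= 0.0:
        raise ValueError("A_tot must be >= 0 and R1_tot, Kd1 > 0")
    if not 0.0 <= beta < 1.0:
        raise ValueError(f"beta must lie in [0, 1), got {beta!r}")
    if A_tot == 0.0:
        return 0.0
    K = Kd1 / (1.0 - beta)
    b = A_tot + R1_tot + K
    s = math.sqrt(max(b * b - 4.0 * A_tot * R1_tot, 0.0))
    d = A_tot - R1_tot - K
    if d >= 0.0:
        return 0.5 * (1.0 - beta) * (d + s)
    # s^2 - d^2 = 4 A_tot K, so d + s = 4 A_tot K / (s - d)
    return 0.5 * (1.0 - beta) * 4.0 * A_tot * K / (s - d)


def atot_from_au(A_u: float, R1_tot: float, Kd1: float, beta: float) -> float:
    """Total adenosine from the unbound pool (inverse of :func:`au_from_atot`).

    ``A_tot = A_u (A_u + Kd1 + R1_tot (1-beta)) / ((A_u + Kd1) (1-beta))``.
    """
    if A_u < 0.0 or R1_tot <= 0.0 or Kd1 <= 0.0:
        raise ValueError("A_u must be >= 0 and R1_tot, Kd1 > 0")
    if not 0.0 <= beta < 1.0:
        raise ValueError(f"beta must lie in [0, 1), got {beta!r}")
    return (A_u * (A_u + Kd1 + R1_tot * (1.0 - beta))
            / ((A_u + Kd1) * (1.0 - beta)))


def typical_atot_coefficients(T: float = 8.0, chi_wake: float = 18.18,
                              chi_sleep: float = 4.20) -> Tuple[float, float]:
    """Coefficients (c_w, c_s) with typical A_tot = c_w*mu_wake + c_s*mu_sleep.

    The typical concentration is the plain average of the sleep-onset and
    wake-onset boundary values of the periodic fixed point; because that
    fixed point is affine in (mu_wake, mu_sleep), the coefficients depend
    only on T and the time constants, and sum to exactly 1.
    """
    if not 0.0 < T < 24.0:
        raise ValueError(f"T must lie in (0, 24), got {T!r}")
    if chi_wake <= 0.0 or chi_sleep <= 0.0:
        raise ValueError("time constants must be > 0")
    ew = math.exp((T - 24.0) / chi_wake)
    es = math.exp(-T / chi_sleep)
    den = 1.0 - ew * es
    c_w = (1.0 - ew) * (1.0 + es) / (2.0 * den)
    c_s = (1.0 - es) * (1.0 + ew) / (2.0 * den)
    return c_w, c_s


def periodic_initials(T: float, params: ModelParameters) -> PeriodicBoundary:
    """Fixed point of the alternating wake/sleep exponential relaxations.

    For a regular 24 h cycle with ``T`` hours of sleep, continuity of the
    exact segment solutions across both transitions determines the unique
    periodic boundary values of ``A_tot`` at sleep onset and wake onset.
    """
    if not 0.0 < T < 24.0:
        raise ValueError(f"T must lie in (0, 24), got {T!r}")
    ew = math.exp((T - 24.0) / params.chi_wake)
    es = math.exp(-T / params.chi_sleep)
    den = 1.0 - ew * es
    mw, ms = params.mu_wake, params.mu_sleep
    A_sleep0 = (mw * (1.0 - ew) + ms * (1.0 - es) * ew) / den
    A_wake0 = (ms * (1.0 - es) + mw * (1.0 - ew) * es) / den
    return PeriodicBoundary(T=T, A_sleep0=A_sleep0, A_wake0=A_wake0)


def equilibrium_receptor_total(A_mean: float, params: ModelParameters,
                               tol: float = 1e-10, max_iters: int = 200,
                               ) -> float:
    """R1_tot at which the receptor pool is in equilibrium with ``A_mean``.

    Solves ``A1_b(A_mean, R) = gamma * R`` by bisection on the occupancy,
    which decreases monotonically in R.  Used to initialize limit-cycle
    iteration without a multi-week burn-in transient.
    """
    if A_mean < 0.0:
        raise ValueError("A_mean must be >= 0")
    K = params.Kd1 / (1.0 - params.beta)

    def occupancy(R: float) -> float:
        return _a1b_root(A_mean, R, K) / R

    lo, hi = 1e-6, max(A_mean, 1.0)
    if occupancy(lo) <= params.gamma:
        # mean adenosine too low to sustain the target occupancy at any
        # receptor level; fall back to a small pool
        return lo
    for _ in range(200):
        if occupancy(hi) < params.gamma:
            break
        hi *= 2.0
    else:
        raise ConvergenceError("could not bracket equilibrium receptor total")
    for _ in range(max_iters):
        mid = 0.5 * (lo + hi)
        if occupancy(mid) > params.gamma:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def _run_forced_day(A: float, R: float, schedule: Schedule,
                    params: ModelParameters, dt: float) -> Tuple[float, float]:
    """One pass of a repeating forced 24 h schedule; returns boundary (A, R)."""
    for seg in schedule.segments:
        mode = WAKE if seg.mode == FORCED_WAKE else SLEEP
        _, A, R = _advance(0.0, A, R, mode, seg.duration, params, dt)
    return A, R


def limit_cycle(schedule_one_day: Schedule, params: ModelParameters,
                tol: float = 1e-8, max_iters: int = 400,
                dt: float = DEFAULT_DT) -> SystemState:
    """Converge a repeating 24 h forced schedule to its limit cycle.

    The day map is iterated until the relative change of (A_tot, R1_tot)
    at the day boundary falls below ``tol``; because the receptor time
    constant makes the map a slow contraction, Aitken extrapolation is
    applied every third iterate (the convergence test is always on the
    plain day map, so the returned state satisfies the fixed-point
    contract at ``tol``).

    Returns the converged boundary state at t = 0 with the vigilance of
    the schedule's first segment.
    """
    if abs(schedule_one_day.duration - 24.0) > 1e-9:
        raise ConfigError("limit_cycle requires a 24 h schedule")
    for seg in schedule_one_day.segments:
        if seg.mode not in (FORCED_WAKE, FORCED_SLEEP):
            raise ConfigError("limit_cycle requires a forced-only schedule")

    wake_h = sum(s.duration for s in schedule_one_day.segments
                 if s.mode == FORCED_WAKE)
    A = (wake_h * params.mu_wake + (24.0 - wake_h) * params.mu_sleep) / 24.0
    # one throwaway day to get a sensible schedule-average A_tot
    A, _ = _run_forced_day(A, 600.0, schedule_one_day, params, dt)
    R = equilibrium_receptor_total(A, params)

    hist: list = []
    for it in range(max_iters):
        A1, R1 = _run_forced_day(A, R, schedule_one_day, params, dt)
        rel = max(abs(A1 - A) / max(abs(A1), 1e-12),
                  abs(R1 - R) / max(abs(R1), 1e-12))
        if rel < tol:
            vig = (WAKE if schedule_one_day.segments[0].mode == FORCED_WAKE
                   else SLEEP)
            return SystemState(t=0.0, A_tot=A1, R1_tot=R1, vigilance=vig)
        hist.append((A1, R1))
        if len(hist) >= 3:
            (a0, r0), (a1_, r1_), (a2, r2) = hist[-3:]
            A1 = _aitken(a0, a1_, a2)
            R1 = _aitken(r0, r1_, r2)
            if not (math.isfinite(A1) and math.isfinite(R1)
                    and A1 > 0.0 and R1 > 0.0):
                A1, R1 = a2, r2
            hist.clear()
        A, R = A1, R1
    raise ConvergenceError(
        f"limit cycle did not converge within {max_iters} day iterations"
    )


def _aitken(x0: float, x1: float, x2: float) -> float:
    denom = x2 - 2.0 * x1 + x0
    if abs(denom) < 1e-300:
        return x2
    return x2 - (x2 - x1) ** 2 / denom
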