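"""Compiled inner loops for the slow-state integrator.

The model is integrated with a fixed-step scheme (exact exponential update
for total adenosine, RK4 for the receptor pool, quadratic-root binding
solve at every stage); grid searches and staged fits evaluate tens of
thousands of multi-week simulations, so the per-step work lives in numba
kernels.  Semantics here define the integrator; the pure-Python wrappers
in :mod:`adenosim.core` and :mod:`adenosim.behavior` only marshal states
and bouts.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

#: bisection tolerance on threshold-crossing times (h)
TRANSITION_TOL = 1e-6


@njit(cache=False)
def a1b_root(A: float, R: float, K: float) -> float:
    """Smaller (physical) root of the bound-A1 quadratic, stable form."""
    if A <= 0.0:
        return 0.0
    b = A + R + K
    disc = b * b - 4.0 * A * R
    if disc < 0.0:
        disc = 0.0
    return 2.0 * A * R / (b + math.sqrt(disc))


@njit(cache=False)
def rk4_step(A, R, h, mu, chi, K, gamma, lam):
    """One RK4 step on R1_tot with A_tot advanced by its exact solution."""
    fh = math.exp(-0.5 * h / chi)
    dA = A - mu
    A_half = mu + dA * fh
    A_end = mu + dA * fh * fh
    k1 = (a1b_root(A, R, K) - gamma * R) / lam
    r = R + 0.5 * h * k1
    k2 = (a1b_root(A_half, r, K) - gamma * r) / lam
    r = R + 0.5 * h * k2
    k3 = (a1b_root(A_half, r, K) - gamma * r) / lam
    r = R + h * k3
    k4 = (a1b_root(A_end, r, K) - gamma * r) / lam
    return A_end, R + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=False)
def advance_forced(A, R, duration, dt, mu, chi, K, gamma, lam):
    """Advance through a forced segment without recording; returns (A, R)."""
    n_full = int(math.floor(duration / dt + 1e-9))
    rem = duration - n_full * dt
    if rem < 1e-12:
        rem = 0.0
    for _ in range(n_full):
        A, R = rk4_step(A, R, dt, mu, chi, K, gamma, lam)
    if rem > 0.0:
        A, R = rk4_step(A, R, rem, mu, chi, K, gamma, lam)
    return A, R


@njit(cache=False)
def advance_forced_rec(t, A, R, duration, dt, mu, chi, K, gamma, lam,
                       out_t, out_A, out_R):
    """Advance through a forced segment recording every step endpoint.

    Returns (n_recorded, A_end, R_end).  The starting point is not
    recorded; the final timestamp is exactly ``t + duration``.
    """
    t_end = t + duration
    n_full = int(math.floor(duration / dt + 1e-9))
    rem = duration - n_full * dt
    if rem < 1e-12:
        rem = 0.0
    m = 0
    for _ in range(n_full):
        A, R = rk4_step(A, R, dt, mu, chi, K, gamma, lam)
        t += dt
        out_t[m] = t
        out_A[m] = A
        out_R[m] = R
        m += 1
    if rem > 0.0:
        A, R = rk4_step(A, R, rem, mu, chi, K, gamma, lam)
        out_t[m] = t_end
        out_A[m] = A
        out_R[m] = R
        m += 1
    elif m > 0:
        out_t[m - 1] = t_end  # snap accumulated float drift
    return m, A, R


@njit(cache=False)
def free_window(t0, A, R, awake, t_end, dt,
                mu_w, chi_w, mu_s, chi_s, K, gamma, lam,
                amp, phi, omega, d_sleep, d_wake,
                out_t, out_A, out_R, out_awake,
                out_onset, out_offset):
    """Two-threshold free-sleep window.

    Applies the hysteretic switching rule: transition to sleep when the
    drive rises through ``d_sleep`` while awake, to wake when it falls
    through ``d_wake`` while asleep; between the thresholds the current
    vigilance persists.  Crossing times are refined by bisection (one RK4
    sub-step from the bracketing gridpoint) to ``TRANSITION_TOL``.

    Records every step endpoint and every transition point (the entry
    state is not recorded).  A bout still open at the window end is
    closed there.  Returns (n_recorded, n_bouts, A, R, awake_end).
    """
    t = t0
    m = 0
    nb = 0
    open_onset = t0 if not awake else np.nan

    # immediate transition at entry
    D0 = a1b_root(A, R, K) + amp * math.cos(omega * (t - phi))
    if awake and D0 >= d_sleep:
        awake = False
        open_onset = t
        out_t[m] = t
        out_A[m] = A
        out_R[m] = R
        out_awake[m] = False
        m += 1
    elif (not awake) and D0 <= d_wake:
        awake = True
        if not math.isnan(open_onset) and t > open_onset:
            out_onset[nb] = open_onset
            out_offset[nb] = t
            nb += 1
        open_onset = np.nan
        out_t[m] = t
        out_A[m] = A
        out_R[m] = R
        out_awake[m] = True
        m += 1

    while t < t_end - 1e-12:
        h = dt if t + dt <= t_end else t_end - t
        if awake:
            mu, chi = mu_w, chi_w
        else:
            mu, chi = mu_s, chi_s
        A1, R1 = rk4_step(A, R, h, mu, chi, K, gamma, lam)
        D1 = a1b_root(A1, R1, K) + amp * math.cos(omega * (t + h - phi))
        crossed = (awake and D1 >= d_sleep) or ((not awake) and D1 <= d_wake)
        if not crossed:
            t += h
            if t_end - t < 1e-12:
                t = t_end  # snap accumulated float error at the boundary
            A, R = A1, R1
            out_t[m] = t
            out_A[m] = A
            out_R[m] = R
            out_awake[m] = awake
            m += 1
            continue
        thr = d_sleep if awake else d_wake
        sign = 1.0 if awake else -1.0
        lo = 0.0
        hi = h
        while hi - lo > TRANSITION_TOL:
            mid = 0.5 * (lo + hi)
            Am, Rm = rk4_step(A, R, mid, mu, chi, K, gamma, lam)
            Dm = a1b_root(Am, Rm, K) + amp * math.cos(
                omega * (t + mid - phi))
            if sign * (Dm - thr) >= 0.0:
                hi = mid
            else:
                lo = mid
        tau = 0.5 * (lo + hi)
        A, R = rk4_step(A, R, tau, mu, chi, K, gamma, lam)
        t += tau
        out_t[m] = t
        out_A[m] = A
        out_R[m] = R
        out_awake[m] = awake
        m += 1
        # switch vigilance
        if awake:
            awake = False
            open_onset = t
        else:
            awake = True
            if not math.isnan(open_onset) and t > open_onset:
                out_onset[nb] = open_onset
                out_offset[nb] = t
                nb += 1
            open_onset = np.nan
        out_t[m] = t
        out_A[m] = A
        out_R[m] = R
        out_awake[m] = awake
        m += 1

    if (not awake) and (not math.isnan(open_onset)) and t_end > open_onset:
        out_onset[nb] = open_onset
        out_offset[nb] = t_end
        nb += 1
    return m, nb, A, R, awake
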