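"""Slow-state integration of the adenosine receptor-ligand system.

Two slow state variables are integrated through arbitrary sleep/wake
histories: total adenosine concentration ``A_tot`` (first-order kinetics,
``chi * dA_tot/dt = mu - A_tot`` with state-dependent ``mu`` and ``chi``)
and total A1 receptor concentration ``R1_tot`` (occupancy homeostasis,
``lambda * dR1_tot/dt = R1_b - gamma * R1_tot``).  Binding and unbinding
are fast compared with both, so at every instant the bound/unbound pools
are resolved by the quasistatic equilibrium of the mass-action kinetics.

Numerical scheme: ``A_tot`` is advanced with its exact exponential
solution within constant-vigilance segments; ``R1_tot`` with fixed-step
classical RK4 (default step 0.01 h), recomputing the bound pool at every
RK4 stage.  The receptor equation is slow (lambda ~ 291 h) and non-stiff,
so a fixed step keeps results bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels as _k
from .errors import ConvergenceError
from .params import ModelParameters

__all__ = [
    "WAKE",
    "SLEEP",
    "DEFAULT_DT",
    "SystemState",
    "BindingEquilibrium",
    "atot_exact",
    "binding_equilibrium",
    "receptor_rate",
    "integrate_segment",
    "kinetic_oracle",
]

WAKE = "wake"
SLEEP = "sleep"

#: Default fixed RK4 step (h).
DEFAULT_DT = 0.01


@dataclass(frozen=True)
class SystemState:
    """Slow state of the system at one instant.

    ``t`` is absolute time in hours from simulation start; clock time is
    ``t mod 24`` with 0 = midnight.  All bound/unbound pools are derived
    from ``A_tot`` and ``R1_tot`` via :func:`binding_equilibrium`.
    """

    t: float
    A_tot: float
    R1_tot: float
    vigilance: str

    def __post_init__(self) -> None:
        if self.vigilance not in (WAKE, SLEEP):
            raise ValueError(f"vigilance must be {WAKE!r} or {SLEEP!r}")
        if self.A_tot < 0.0:
            raise ValueError(f"A_tot must be >= 0, got {self.A_tot!r}")
        if self.R1_tot <= 0.0:
            raise ValueError(f"R1_tot must be > 0, got {self.R1_tot!r}")


@dataclass(frozen=True)
class BindingEquilibrium:
    """Quasistatic fractionation of adenosine and receptors into pools.

    Satisfies the conservation laws ``A_u + A1_b + A2_b = A_tot`` and
    ``R1_u + R1_b = R1_tot`` and the dissociation relation
    ``A_u * R1_u / R1_b = Kd1``.  Bound receptor pools equal the
    corresponding bound adenosine pools by definition.
    """

    A_u: float
    A1_b: float
    A2_b: float
    R1_u: float
    R1_b: float
    R2_u: float
    R2_b: float
    beta: float


def atot_exact(A0: float, mu: float, chi: float, dt: float) -> float:
    """Exact segment solution of the total-adenosine kinetics.

    ``A(dt) = mu + (A0 - mu) * exp(-dt/chi)``: exponential relaxation from
    ``A0`` toward the saturation value ``mu`` with time constant ``chi``.
    """
    if not chi > 0.0:
        raise ValueError(f"chi must be > 0, got {chi!r}")
    if dt < 0.0:
        raise ValueError(f"dt must be >= 0, got {dt!r}")
    return mu + (A0 - mu) * math.exp(-dt / chi)


def _a1b_root(A: float, R: float, K: float) -> float:
    """Smaller root of ``x^2 - (A + R + K) x + A R = 0`` (bound A1 pool).

    ``K = Kd1 / (1 - beta)`` is the A1 dissociation constant inflated by
    the competing A2A pathway.  Evaluated as ``2AR / (b + sqrt(b^2-4AR))``,
    which is algebraically the "-" branch of the quadratic formula but
    avoids the catastrophic cancellation of the printed form when
    ``A R >> K``.  The smaller root is the physical one: it satisfies
    ``0 <= A1_b <= min(A_tot, R1_tot)`` (the larger root exceeds both).
    """
    if A <= 0.0:
        return 0.0
    b = A + R + K
    disc = b * b - 4.0 * A * R
    # disc = (A-R)^2 + K^2 + 2K(A+R) >= 0 for valid inputs.
    assert disc >= -1e-9 * b * b, "negative discriminant for valid inputs"
    if disc < 0.0:
        disc = 0.0
    return 2.0 * A * R / (b + math.sqrt(disc))


def binding_equilibrium(A_tot, R1_tot, params: ModelParameters):
    """Resolve the instantaneous bound/unbound pools.

    Accepts scalars or numpy arrays (broadcast together).  The unbound
    A2A pool is held at ``R2_tot`` when computing the partition fraction
    ``beta``, consistent with the low A2A affinity.

    Returns a :class:`BindingEquilibrium`; with array inputs its fields
    are arrays.
    """
    A = np.asarray(A_tot, dtype=float)
    R = np.asarray(R1_tot, dtype=float)
    if np.any(A < 0.0):
        raise ValueError("A_tot must be >= 0")
    if np.any(R <= 0.0):
        raise ValueError("R1_tot must be > 0")
    beta = params.beta
    K = params.Kd1 / (1.0 - beta)
    b = A + R + K
    disc = b * b - 4.0 * A * R
    assert np.all(disc >= -1e-9 * b * b)
    A1_b = 2.0 * A * R / (b + np.sqrt(np.maximum(disc, 0.0)))
    A2_b = beta * (A - A1_b)
    A_u = A - A1_b - A2_b
    R1_u = R - A1_b
    R2_u = np.broadcast_to(np.asarray(params.R2_tot, dtype=float), A1_b.shape)
    scalar = np.ndim(A_tot) == 0 and np.ndim(R1_tot) == 0
    if scalar:
        return BindingEquilibrium(
            A_u=float(A_u), A1_b=float(A1_b), A2_b=float(A2_b),
            R1_u=float(R1_u), R1_b=float(A1_b),
            R2_u=float(params.R2_tot), R2_b=float(A2_b), beta=beta,
        )
    return BindingEquilibrium(
        A_u=A_u, A1_b=A1_b, A2_b=A2_b, R1_u=R1_u, R1_b=A1_b.copy(),
        R2_u=np.array(R2_u), R2_b=A2_b.copy(), beta=beta,
    )


def receptor_rate(R1_b: float, R1_tot: float, params: ModelParameters) -> float:
    """Right-hand side of the A1 receptor homeostasis equation (nM/h).

    Zero exactly at the target occupancy ``R1_b = gamma * R1_tot``;
    positive (up-regulation) above it, negative below.
    """
    if np.any(np.asarray(R1_tot) <= 0.0):
        raise ValueError("R1_tot must be > 0")
    return (R1_b - params.gamma * R1_tot) / params.lambda_


def _segment_coeffs(mode: str, params: ModelParameters) -> tuple:
    """(mu, chi, K, gamma, lambda) for one constant-vigilance segment."""
    if mode == WAKE:
        mu, chi = params.mu_wake, params.chi_wake
    elif mode == SLEEP:
        mu, chi = params.mu_sleep, params.chi_sleep
    else:
        raise ValueError(f"unknown vigilance mode {mode!r}")
    K = params.Kd1 / (1.0 - params.beta)
    return mu, chi, K, params.gamma, params.lambda_


def _advance(t: float, A: float, R: float, mode: str, duration: float,
             params: ModelParameters, dt: float,
             record: list | None = None) -> tuple:
    """Advance (t, A_tot, R1_tot) through one constant-vigilance span.

    ``record``, if given, is a list to which (t, A, R) tuples are appended
    after every step (the starting point is *not* appended).  The final
    timestamp equals ``t + duration`` exactly (last step truncated).
    """
    if duration < 0.0:
        raise ValueError("duration must be >= 0")
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    mu, chi, K, gamma, lam = _segment_coeffs(mode, params)
    t_end = t + duration
    if record is None:
        A, R = _k.advance_forced(A, R, duration, dt, mu, chi, K, gamma, lam)
        return t_end, A, R
    n_max = int(duration / dt) + 2
    out_t = np.empty(n_max)
    out_A = np.empty(n_max)
    out_R = np.empty(n_max)
    m, A, R = _k.advance_forced_rec(t, A, R, duration, dt, mu, chi, K,
                                    gamma, lam, out_t, out_A, out_R)
    for i in range(m):
        record.append((out_t[i], out_A[i], out_R[i]))
    return t_end, A, R


def _advance_arrays(t: float, A: float, R: float, mode: str,
                    duration: float, params: ModelParameters, dt: float,
                    ) -> tuple:
    """Like :func:`_advance` with recording, returning trimmed arrays."""
    if duration < 0.0:
        raise ValueError("duration must be >= 0")
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    mu, chi, K, gamma, lam = _segment_coeffs(mode, params)
    n_max = int(duration / dt) + 2
    out_t = np.empty(n_max)
    out_A = np.empty(n_max)
    out_R = np.empty(n_max)
    m, A, R = _k.advance_forced_rec(t, A, R, duration, dt, mu, chi, K,
                                    gamma, lam, out_t, out_A, out_R)
    return out_t[:m], out_A[:m], out_R[:m], A, R


def integrate_segment(state: SystemState, mode: str, duration: float,
                      params: ModelParameters, dt: float = DEFAULT_DT,
                      ) -> List[SystemState]:
    """Integrate one constant-vigilance segment; returns the gridded states.

    The returned list starts with ``state`` (its vigilance replaced by
    ``mode``) and ends with the state at ``state.t + duration`` exactly.
    ``A_tot`` is continuous across segment boundaries by construction.
    """
    rec: list = []
    start = SystemState(state.t, state.A_tot, state.R1_tot, mode)
    _advance(state.t, state.A_tot, state.R1_tot, mode, duration, params, dt,
             record=rec)
    out = [start]
    for (t, A, R) in rec:
        out.append(SystemState(t, A, R, mode))
    if duration > 0.0 and out[-1].t != start.t + duration:
        # duration smaller than one step and no remainder recorded
        t, A, R = _advance(state.t, state.A_tot, state.R1_tot, mode, duration,
                           params, dt)
        out.append(SystemState(t, A, R, mode))
    return out


def kinetic_oracle(A_tot: float, R1_tot: float, params: ModelParameters,
                   k1b: float = 1.0, k2b: float = 1.0,
                   deriv_tol: float = 1e-10, max_chunks: int = 64,
                   ) -> BindingEquilibrium:
    """Equilibrate the explicit mass-action binding kinetics (test oracle).

    Integrates the three binding/unbinding ODEs for (A_u, R1_b, R2_b) from
    an all-unbound start until the maximum absolute time derivative falls
    below ``deriv_tol`` (nM/h).  Unbinding rates are tied to the
    dissociation constants, ``k_nu = Kd_n * k_nb``, so the equilibrium
    depends only on the Kd ratios, not on the individual rate magnitudes.
    The unbound A2A pool is held at ``R2_tot``, the same assumption the
    quasistatic reduction makes.

    This routine is deliberately independent of :func:`binding_equilibrium`
    and serves as its brute-force cross-check.
    """
    if k1b <= 0.0 or k2b <= 0.0:
        raise ValueError("binding rate constants must be > 0")
    if A_tot < 0.0 or R1_tot <= 0.0:
        raise ValueError("invalid concentrations")
    k1u = params.Kd1 * k1b
    k2u = params.Kd2 * k2b
    R2u = params.R2_tot  # frozen unbound A2A pool

    def rhs(_t, y):
        Au, R1b, R2b = y
        R1u = R1_tot - R1b
        bind1 = k1b * Au * R1u
        bind2 = k2b * Au * R2u
        return [-bind1 - bind2 + k1u * R1b + k2u * R2b,
                bind1 - k1u * R1b,
                bind2 - k2u * R2b]

    y = [float(A_tot), 0.0, 0.0]
    # Relaxation rate is at least k1u = Kd1*k1b, so chunks of a few
    # relaxation times suffice.
    chunk = 10.0 / min(k1u, k2u, k1b, k2b)
    for _ in range(max_chunks):
        d = rhs(0.0, y)
        if max(abs(v) for v in d) < deriv_tol:
            Au, R1b, R2b = y
            return BindingEquilibrium(
                A_u=Au, A1_b=R1b, A2_b=R2b, R1_u=R1_tot - R1b, R1_b=R1b,
                R2_u=R2u, R2_b=R2b, beta=R2u / (R2u + params.Kd2),
            )
        sol = solve_ivp(rhs, (0.0, chunk), y, method="LSODA",
                        rtol=1e-12, atol=1e-12)
        if not sol.success:
            raise ConvergenceError(f"mass-action integration failed: {sol.message}")
        y = [float(v) for v in sol.y[:, -1]]
    raise ConvergenceError(
        "mass-action kinetics did not reach steady state within budget"
    )
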