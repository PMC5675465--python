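"""Staged parameter estimation and goodness-of-fit metrics.

The calibration workflow has three stages, mirroring how the model's
parameters are identified by the two experiments:

1. **PVT stage** — with the receptor time constant held at a nominal
   value, the adenosine/receptor and performance parameters are fit to
   PVT lapse counts on forced schedules (acute deprivation and chronic
   restriction) by Levenberg-Marquardt least squares inside their
   physiological ranges (box constraints handled by smooth
   reparameterization).
2. **Sleep-timing stage** — the receptor time constant and the two
   sleep/wake thresholds are fit to daily sleep durations in the
   long-night protocol by exhaustive grid search with successive
   refinement (the least-squares landscape is too flat for LM here).
3. **Recalibration** — the performance sigmoid midpoint and width are
   refit against the PVT data; the sigmoid does not feed back on
   sleep/wake outputs, so the stage-2 fit is untouched.

Each stage is a scikit-learn style estimator (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with trailing
underscores); the module-level ``fit_stage*`` functions are thin wrappers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .analytics import gamma_target, limit_cycle
from .behavior import daily_sleep_durations, pvt_lapses, sleep_drive
from .core import SystemState, binding_equilibrium
from .errors import ConfigError
from .params import ModelParameters
from .protocol import (ProtocolSpec, build_exp1, build_exp2,
                       pvt_sample_times)
from .simulate import run_schedule_bouts, simulate_schedule, states_at_times

__all__ = [
    "FitResult",
    "adjusted_r2",
    "rmse",
    "objective_pvt",
    "PVTStage1Estimator",
    "SleepTimingStage2Estimator",
    "SigmoidRecalibrationEstimator",
    "stage1_consistent_params",
    "fit_stage1",
    "fit_stage2",
    "fit_stage3_recalibrate",
]

#: Default integration step (h) for model evaluations inside fits; the
#: receptor equation is smooth and slow, so RK4 error at this step is far
#: below observation noise.
FIT_DT = 0.02

#: Typical mean unbound adenosine (nM) used when tying gamma to Kd1.
AU_TYPICAL = 30.0

_ALIGN_TOL = 1e-6


@dataclass
class FitResult:
    """Outcome of one fitting stage."""

    parameters: ModelParameters
    sse: float
    adjusted_r2: float
    rmse: float
    n_obs: int
    n_params: int
    converged: bool
    n_iterations: int
    message: str = ""
    boundary_active: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "sse": self.sse,
            "adjusted_r2": self.adjusted_r2,
            "rmse": self.rmse,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "message": self.message,
            "boundary_active": list(self.boundary_active),
        }


def rmse(observed, predicted) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def adjusted_r2(observed, predicted, n_params: int) -> float:
    """Wherry/Ezekiel adjusted R-squared.

    ``1 - (1 - R^2) (n - 1) / (n - p - 1)`` with ``p`` the number of free
    parameters of the stage.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = observed.size
    if n <= n_params + 1:
        raise ValueError("need n_obs > n_params + 1 for adjusted R^2")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst <= 0.0:
        raise ValueError("degenerate variance in observations")
    sse = float(np.sum((observed - predicted) ** 2))
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


# ---------------------------------------------------------------------------
# observation handling and prediction
# ---------------------------------------------------------------------------

def _check_observations(obs: pd.DataFrame) -> pd.DataFrame:
    required = {"condition", "time_h", "value"}
    if not required.issubset(obs.columns):
        raise ConfigError(
            f"observations need columns {sorted(required)}, "
            f"got {list(obs.columns)}"
        )
    return obs


def _protocols_for(conditions: Sequence[str]) -> Dict[str, ProtocolSpec]:
    return {c: build_exp1(c) for c in conditions}


def _align_times(obs: pd.DataFrame,
                 protos: Dict[str, ProtocolSpec]) -> Dict[str, np.ndarray]:
    """Validate observation times against each protocol's sampling grid."""
    times_by_cond: Dict[str, np.ndarray] = {}
    for cond, grp in obs.groupby("condition", sort=True):
        if cond not in protos:
            raise ConfigError(f"unknown condition {cond!r} in observations")
        proto = protos[cond]
        grid = pvt_sample_times(proto.schedule,
                                start=proto.t_condition_start)
        t = np.sort(np.asarray(grp["time_h"], dtype=float))
        if not np.all(np.diff(t) > 0):
            raise ConfigError(f"duplicate observation times for {cond!r}")
        nearest = np.abs(t[:, None] - grid[None, :]).min(axis=1)
        if np.any(nearest > _ALIGN_TOL):
            bad = t[nearest > _ALIGN_TOL]
            raise ConfigError(
                f"observation times for {cond!r} misaligned with the PVT "
                f"sampling grid: {bad[:5]}"
            )
        times_by_cond[cond] = t
    return times_by_cond


def _predict_pvt(params: ModelParameters,
                 protos: Dict[str, ProtocolSpec],
                 times_by_cond: Dict[str, np.ndarray],
                 dt: float) -> Dict[str, np.ndarray]:
    """Predicted lapse counts per condition at the given sample times.

    All conditions share the same initialization recipe, so the limit
    cycle is computed once per parameter set.
    """
    first = next(iter(protos.values()))
    init = limit_cycle(first.init_day, params, dt=dt)
    out: Dict[str, np.ndarray] = {}
    for cond, proto in protos.items():
        start = SystemState(proto.schedule.start, init.A_tot, init.R1_tot,
                            init.vigilance)
        t = times_by_cond[cond]
        A, R = states_at_times(proto.schedule, params, t, start, dt=dt)
        R1b = binding_equilibrium(A, R, params).R1_b
        D = sleep_drive(R1b, t, params)
        out[cond] = pvt_lapses(D, params)
    return out


def objective_pvt(params: ModelParameters,
                  protos: Dict[str, ProtocolSpec],
                  observations: pd.DataFrame,
                  dt: float = FIT_DT) -> np.ndarray:
    """Residual vector (predicted - observed lapses) across conditions.

    Observation times must lie on each protocol's PVT sampling grid;
    misalignment raises :class:`ConfigError`.  The sum of squared
    residuals is invariant to observation ordering (conditions are
    traversed in sorted order, times ascending).
    """
    obs = _check_observations(observations)
    times_by_cond = _align_times(obs, protos)
    preds = _predict_pvt(params, protos, times_by_cond, dt)
    res: List[np.ndarray] = []
    for cond in sorted(times_by_cond):
        grp = obs[obs["condition"] == cond].sort_values("time_h")
        res.append(preds[cond] - np.asarray(grp["value"], dtype=float))
    return np.concatenate(res) if res else np.empty(0)


# ---------------------------------------------------------------------------
# smooth reparameterizations for box/ordering constraints
# ---------------------------------------------------------------------------

class _Transform:
    """Map an unconstrained optimizer coordinate to a parameter value."""

    def to_value(self, z: float, ctx: dict) -> float:
        raise NotImplementedError

    def to_z(self, value: float, ctx: dict) -> float:
        raise NotImplementedError

    def at_boundary(self, value: float) -> bool:
        return False


class _Box(_Transform):
    def __init__(self, lo: float, hi: float, log: bool = False):
        self.lo, self.hi, self.log = lo, hi, log

    def _bounds(self):
        if self.log:
            return math.log(self.lo), math.log(self.hi)
        return self.lo, self.hi

    def to_value(self, z, ctx):
        lo, hi = self._bounds()
        frac = min(max(float(expit(z)), 1e-9), 1.0 - 1e-9)
        v = lo + (hi - lo) * frac
        return math.exp(v) if self.log else v

    def to_z(self, value, ctx):
        lo, hi = self._bounds()
        v = math.log(value) if self.log else value
        frac = min(max((v - lo) / (hi - lo), 1e-6), 1.0 - 1e-6)
        return float(logit(frac))

    def at_boundary(self, value):
        span = self.hi - self.lo
        return (value - self.lo) < 1e-3 * span or (self.hi - value) < 1e-3 * span


class _Positive(_Transform):
    def to_value(self, z, ctx):
        # clamp so trial steps far outside the plausible region stay finite
        return math.exp(min(max(z, -50.0), 50.0))

    def to_z(self, value, ctx):
        return math.log(max(value, 1e-12))


class _Identity(_Transform):
    def to_value(self, z, ctx):
        return z

    def to_z(self, value, ctx):
        return value


class _RatioOf(_Transform):
    """value = ctx[other] * sigmoid(z); enforces 0 < value < ctx[other]."""

    def __init__(self, other: str):
        self.other = other

    def to_value(self, z, ctx):
        frac = min(max(float(expit(z)), 1e-9), 1.0 - 1e-9)
        return ctx[self.other] * frac

    def to_z(self, value, ctx):
        frac = min(max(value / ctx[self.other], 1e-6), 1.0 - 1e-6)
        return float(logit(frac))


class _DriveOffset(_Transform):
    """Sigmoid midpoint as an offset from the model's baseline drive.

    The operating point of the sleep drive is set by the bound-receptor
    level the other parameters imply (roughly ``A_typ - Au*/(1-beta)``
    with ``Au* = Kd1 gamma/(1-gamma)`` the unbound level at target
    occupancy and ``A_typ`` the typical total adenosine of a regular
    8 h-sleep day).  Fitting ``D_mid`` as an offset from that reference
    keeps the sigmoid on its operating point for any trial values of the
    physiological parameters; a fixed absolute ``D_mid`` would leave the
    objective flat (saturated sigmoid) over most of the search space.
    """

    @staticmethod
    def _ref(ctx) -> float:
        from .analytics import typical_atot_coefficients
        beta = ctx["R2_tot"] / (ctx["R2_tot"] + ctx["Kd2"])
        c_w, c_s = typical_atot_coefficients(8.0, ctx["chi_wake"],
                                             ctx["chi_sleep"])
        a_typ = c_w * ctx["mu_wake"] + c_s * ctx["mu_sleep"]
        g = ctx["gamma"]
        au_ref = ctx["Kd1"] * g / (1.0 - g)
        return max(a_typ - au_ref / (1.0 - beta), 0.0)

    def to_value(self, z, ctx):
        return self._ref(ctx) + z

    def to_z(self, value, ctx):
        return value - self._ref(ctx)


class _LMResult:
    def __init__(self, x, fun, nfev, status, message, cost_trace):
        self.x = x
        self.fun = fun
        self.nfev = nfev
        self.status = status
        self.message = message
        self.cost_trace = cost_trace


def _damped_lm(fun, z0: np.ndarray, max_nfev: int = 400,
               ftol: float = 1e-10, xtol: float = 1e-10,
               lambda0: float = 1e-3, max_step: float = 3.0,
               fd_step: float = 1e-6) -> _LMResult:
    """Damped Levenberg-Marquardt with Marquardt scaling and a step cap.

    The PVT objective has large saturated-sigmoid plateaus; an
    unrestrained Gauss-Newton step can vault from the basin of attraction
    onto a plateau and stall.  This implementation bounds the step norm
    in the transformed coordinates, uses multiplicative damping on the
    scaled normal equations, and only ever accepts cost-decreasing steps,
    so the objective decreases monotonically across accepted iterations
    (``cost_trace`` records them).
    """
    z = np.asarray(z0, dtype=float).copy()
    r = fun(z)
    nfev = 1
    cost = float(r @ r)
    cost_trace = [cost]
    lam = lambda0
    status, message = 0, "function evaluation budget exhausted"
    n = z.size
    while nfev < max_nfev:
        # forward-difference jacobian
        J = np.empty((r.size, n))
        for j in range(n):
            dz = fd_step * max(1.0, abs(z[j]))
            zj = z.copy()
            zj[j] += dz
            J[:, j] = (fun(zj) - r) / dz
            nfev += 1
        g = J.T @ r
        jtj = J.T @ J
        scale = np.diag(jtj).copy()
        scale[scale <= 0.0] = 1e-12
        accepted = False
        while nfev < max_nfev:
            try:
                p = np.linalg.solve(jtj + lam * np.diag(scale), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            pnorm = float(np.linalg.norm(p))
            if pnorm > max_step:
                p *= max_step / pnorm
            r_new = fun(z + p)
            nfev += 1
            cost_new = float(r_new @ r_new)
            if cost_new < cost:
                accepted = True
                z = z + p
                drop = cost - cost_new
                r, cost = r_new, cost_new
                cost_trace.append(cost)
                lam = max(lam / 3.0, 1e-12)
                if drop <= ftol * max(cost, 1e-300):
                    status, message = 2, "ftol satisfied"
                if pnorm <= xtol * (np.linalg.norm(z) + xtol):
                    status, message = 3, "xtol satisfied"
                break
            lam *= 10.0
            if lam > 1e12:
                status, message = 4, "damping exhausted (flat objective)"
                break
        if status != 0:
            break
        if not accepted:
            status, message = 4, "no acceptable step found"
            break
    if status in (0, 4) and len(cost_trace) > 1:
        # a stall where the last accepted improvement was already
        # negligible is a stationary point, not a failure
        last_drop = cost_trace[-2] - cost_trace[-1]
        if last_drop <= 1e-6 * max(cost_trace[-1], 1e-300):
            status, message = 2, "converged (stationary cost)"
    return _LMResult(z, r, nfev, status, message, cost_trace)


#: Stage-1 transforms; order matters (mu_sleep depends on mu_wake, the
#: D_mid reference on everything physiological before it).
_STAGE1_TRANSFORMS: Dict[str, _Transform] = {
    "Kd1": _Box(1.0, 10.0),
    "Kd2": _Box(100.0, 10000.0, log=True),
    "gamma": _Box(0.75, 0.97),
    "mu_wake": _Box(300.0, 3000.0),
    "mu_sleep": _RatioOf("mu_wake"),
    "D_mid": _DriveOffset(),
    "D_s": _Positive(),
    "a": _Positive(),
    "phi": _Box(0.0, 24.0),
}

_STAGE1_DEFAULT_FREE = (
    "Kd1", "Kd2", "mu_wake", "mu_sleep", "D_mid", "D_s", "a", "phi",
)

#: Typical total A1 receptor concentration (nM) in the human cerebral
#: cortex, used in the typical-concentration constraint on the mu pair.
R1_TYPICAL = 600.0


def _mu_constraint(ctx: dict, au_typical: float,
                   r1_typical: float = R1_TYPICAL) -> Tuple[float, float, float]:
    """(A_typ, c_w, c_s) for the typical-concentration tie on the mus.

    ``A_typ`` is the total adenosine implied by the typical unbound level
    at the typical receptor concentration; the periodic-average identity
    ``c_w mu_wake + c_s mu_sleep = A_typ`` then leaves one degree of
    freedom in the mu pair.
    """
    from .analytics import atot_from_au, typical_atot_coefficients
    beta = ctx["R2_tot"] / (ctx["R2_tot"] + ctx["Kd2"])
    a_typ = atot_from_au(au_typical, r1_typical, ctx["Kd1"], beta)
    c_w, c_s = typical_atot_coefficients(8.0, ctx["chi_wake"],
                                         ctx["chi_sleep"])
    return a_typ, c_w, c_s


def stage1_consistent_params(params: ModelParameters,
                             au_typical: float = AU_TYPICAL,
                             r1_typical: float = R1_TYPICAL,
                             ) -> ModelParameters:
    """Project a parameter set onto the stage-1 constraint surface.

    Ties ``gamma`` to the steady-state occupancy relation and ``mu_sleep``
    to the typical-concentration identity, keeping everything else.  Used
    to construct generating truths for parameter-recovery experiments that
    lie inside the constrained model class.
    """
    ctx = params.to_dict()
    a_typ, c_w, c_s = _mu_constraint(ctx, au_typical, r1_typical)
    mu_sleep = (a_typ - c_w * params.mu_wake) / c_s
    return params.replace(gamma=gamma_target(au_typical, params.Kd1),
                          mu_sleep=mu_sleep)


class PVTStage1Estimator(BaseEstimator):
    """Levenberg-Marquardt fit of the adenosine/performance parameters.

    ``X`` is a DataFrame with columns ``condition`` and ``time_h`` (times
    on the PVT sampling grid of the named forced protocol); ``y`` the
    observed lapse counts.  Box constraints from the physiological ranges
    are enforced by smooth logistic reparameterization so the LM machinery
    runs unmodified; the wake/sleep asymptote ordering is enforced by
    fitting ``mu_sleep`` as a fraction of ``mu_wake``.

    With ``tie_gamma`` (default), the target occupancy is tied to the
    steady-state occupancy relation at the typical unbound adenosine
    level, ``gamma = Au/(Au + Kd1)`` with Au = 30 nM, rather than fit
    freely inside its range.

    Fitted attributes: ``params_`` (full parameter set), ``result_``
    (:class:`FitResult`), ``sse_``, ``n_iter_``.
    """

    def __init__(self, free: Sequence[str] = _STAGE1_DEFAULT_FREE,
                 tie_gamma: bool = True, tie_mu: bool = True,
                 au_typical: float = AU_TYPICAL,
                 r1_typical: float = R1_TYPICAL,
                 start: Optional[ModelParameters] = None,
                 base_params: Optional[ModelParameters] = None,
                 dt: float = FIT_DT, max_nfev: int = 400,
                 xtol: float = 1e-10, ftol: float = 1e-10):
        self.free = free
        self.tie_gamma = tie_gamma
        self.tie_mu = tie_mu
        self.au_typical = au_typical
        self.r1_typical = r1_typical
        self.start = start
        self.base_params = base_params
        self.dt = dt
        self.max_nfev = max_nfev
        self.xtol = xtol
        self.ftol = ftol

    # -- internal ----------------------------------------------------------
    def _ordered_free(self) -> List[str]:
        free = list(self.free)
        unknown = [f for f in free if f not in _STAGE1_TRANSFORMS]
        if unknown:
            raise ConfigError(f"unknown free parameters {unknown}")
        if self.tie_gamma and "gamma" in free:
            raise ConfigError("gamma cannot be free while tie_gamma is set")
        if self.tie_mu:
            # mu_sleep is determined by the typical-concentration identity;
            # with mu_wake also fixed, both mus simply stay at their base
            # values
            free = [f for f in free if f != "mu_sleep"]
        # keep declaration order of _STAGE1_TRANSFORMS (dependency order)
        return [f for f in _STAGE1_TRANSFORMS if f in free]

    def _mu_wake_bounds(self, ctx: dict) -> Tuple[float, float, float, float]:
        """(lo, hi, a_typ, c_w/c_s ratio context) for the tied mu_wake.

        The identity ``c_w mu_wake + c_s mu_sleep = A_typ`` with
        ``mu_wake > mu_sleep > 0`` confines ``mu_wake`` to
        ``(A_typ, A_typ / c_w)``.
        """
        a_typ, c_w, c_s = _mu_constraint(ctx, self.au_typical,
                                         self.r1_typical)
        return a_typ, a_typ / c_w, c_w, c_s

    def _params_from_z(self, z: np.ndarray, free: List[str],
                       base: ModelParameters) -> ModelParameters:
        ctx = base.to_dict()
        if self.tie_gamma:
            ctx["gamma"] = gamma_target(self.au_typical, ctx["Kd1"])
        updates = {}
        for name, zi in zip(free, z):
            if name == "mu_wake" and self.tie_mu:
                lo, hi, c_w, c_s = self._mu_wake_bounds(ctx)
                frac = min(max(float(expit(zi)), 1e-9), 1.0 - 1e-9)
                mu_w = lo + (hi - lo) * frac
                mu_s = (lo - c_w * mu_w) / c_s  # lo == a_typ
                ctx["mu_wake"] = updates["mu_wake"] = mu_w
                ctx["mu_sleep"] = updates["mu_sleep"] = mu_s
                continue
            val = _STAGE1_TRANSFORMS[name].to_value(float(zi), ctx)
            ctx[name] = val
            updates[name] = val
            if self.tie_gamma and name == "Kd1":
                ctx["gamma"] = gamma_target(self.au_typical, val)
        if self.tie_gamma:
            updates["gamma"] = ctx["gamma"]
        return base.replace(**updates)

    def _z_from_params(self, p: ModelParameters, free: List[str],
                       base: ModelParameters) -> np.ndarray:
        """Optimizer coordinates whose image is the projection of ``p``
        onto the constraint surface.

        The context is built sequentially exactly as in
        :meth:`_params_from_z` (ties applied), so the realized starting
        parameters are the requested ones projected into the fitted model
        class — otherwise the start could land far from where the caller
        intended (e.g. in sigmoid saturation).
        """
        ctx = base.to_dict()
        if self.tie_gamma:
            ctx["gamma"] = gamma_target(self.au_typical, ctx["Kd1"])
        out = []
        for name in free:
            if name == "mu_wake" and self.tie_mu:
                lo, hi, c_w, c_s = self._mu_wake_bounds(ctx)
                frac = min(max((p.mu_wake - lo) / (hi - lo), 1e-6),
                           1.0 - 1e-6)
                z = float(logit(frac))
                mu_w = lo + (hi - lo) * frac
                ctx["mu_wake"] = mu_w
                ctx["mu_sleep"] = (lo - c_w * mu_w) / c_s
                out.append(z)
                continue
            tr = _STAGE1_TRANSFORMS[name]
            z = tr.to_z(getattr(p, name), ctx)
            ctx[name] = tr.to_value(z, ctx)
            if self.tie_gamma and name == "Kd1":
                ctx["gamma"] = gamma_target(self.au_typical, ctx[name])
            out.append(z)
        return np.array(out)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        obs = pd.DataFrame({
            "condition": np.asarray(X["condition"]),
            "time_h": np.asarray(X["time_h"], dtype=float),
            "value": np.asarray(y, dtype=float),
        })
        base = self.base_params or ModelParameters.pvt_fit()
        start = self.start or base
        free = self._ordered_free()
        protos = _protocols_for(sorted(obs["condition"].unique()))
        times_by_cond = _align_times(obs, protos)
        y_by_cond = {
            cond: np.asarray(
                obs[obs["condition"] == cond].sort_values("time_h")["value"],
                dtype=float)
            for cond in sorted(times_by_cond)
        }
        y_all = np.concatenate([y_by_cond[c] for c in sorted(y_by_cond)])

        def residuals(z: np.ndarray) -> np.ndarray:
            params = self._params_from_z(z, free, base)
            preds = _predict_pvt(params, protos, times_by_cond, self.dt)
            return np.concatenate(
                [preds[c] - y_by_cond[c] for c in sorted(y_by_cond)]
            )

        z0 = self._z_from_params(start, free, base)
        res = _damped_lm(residuals, z0, max_nfev=self.max_nfev,
                         xtol=self.xtol, ftol=self.ftol)
        params = self._params_from_z(res.x, free, base)
        pred = y_all + res.fun  # residuals = pred - obs
        boundary = tuple(
            name for name in free
            if _STAGE1_TRANSFORMS[name].at_boundary(getattr(params, name))
        )
        sse = float(np.sum(res.fun ** 2))
        self.params_ = params
        self.n_iter_ = int(res.nfev)
        self.sse_ = sse
        self.cost_trace_ = list(res.cost_trace)
        self.result_ = FitResult(
            parameters=params, sse=sse,
            adjusted_r2=adjusted_r2(y_all, pred, len(free)),
            rmse=rmse(y_all, pred), n_obs=int(y_all.size),
            n_params=len(free), converged=bool(res.status in (2, 3)),
            n_iterations=int(res.nfev), message=str(res.message),
            boundary_active=boundary,
        )
        if not self.result_.converged:
            self.result_.message = (
                "optimizer did not converge; best-so-far returned: "
                + self.result_.message
            )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        obs = pd.DataFrame({
            "condition": np.asarray(X["condition"]),
            "time_h": np.asarray(X["time_h"], dtype=float),
        })
        protos = _protocols_for(sorted(obs["condition"].unique()))
        obs["value"] = 0.0
        times_by_cond = _align_times(obs, protos)
        preds = _predict_pvt(self.params_, protos, times_by_cond, self.dt)
        out = np.empty(len(obs), dtype=float)
        for cond, t in times_by_cond.items():
            mask = obs["condition"] == cond
            order = np.argsort(np.asarray(obs.loc[mask, "time_h"], dtype=float))
            vals = np.empty(mask.sum())
            vals[order] = preds[cond]
            out[np.asarray(mask)] = vals
        return out


class SleepTimingStage2Estimator(BaseEstimator):
    """Grid-search fit of (lambda, D_sleep, D_wake) to daily sleep durations.

    Evaluates the long-night protocol's daily total sleep durations on a
    full factorial grid, then recenters and halves the grid around the
    best triple until every axis is resolved to at least ``sig_figs``
    significant figures.  The threshold pair is gridded internally as its
    midpoint ``(D_sleep + D_wake)/2`` and hysteresis gap
    ``D_sleep - D_wake``: the least-squares valley runs along nearly
    constant midpoint with a weakly identified gap, so axis-aligned
    refinement in those coordinates keeps the optimum inside the window.
    Ties are broken toward the smallest lambda, then the smallest
    midpoint, then the smallest gap (axes are traversed in ascending
    order and only strict improvements are accepted).

    ``X`` is the day index (1-based night number), ``y`` the observed
    total sleep duration (h) for that night.

    Fitted attributes: ``lambda_``, ``d_sleep_``, ``d_wake_``, ``sse_``,
    ``spacing_`` (final grid spacing per axis), ``grid_report_`` (per
    refinement level: axes, best point), ``n_evals_``.
    """

    def __init__(self, base_params: Optional[ModelParameters] = None,
                 lambda_range: Tuple[float, float] = (150.0, 450.0),
                 d_sleep_range: Tuple[float, float] = (560.0, 590.0),
                 d_wake_range: Tuple[float, float] = (540.0, 570.0),
                 n_points: int = 5, sig_figs: int = 3, dt: float = FIT_DT,
                 max_levels: int = 14, gap_band: float = 4.0):
        self.base_params = base_params
        self.lambda_range = lambda_range
        self.d_sleep_range = d_sleep_range
        self.d_wake_range = d_wake_range
        self.n_points = n_points
        self.sig_figs = sig_figs
        self.dt = dt
        self.max_levels = max_levels
        self.gap_band = gap_band

    @staticmethod
    def _target_spacing(value: float, sig_figs: int) -> float:
        """Half a unit in the last required significant digit."""
        if value <= 0.0:
            return 1e-3
        exponent = math.floor(math.log10(value)) - (sig_figs - 1)
        return 0.5 * 10.0 ** exponent

    def fit(self, X, y):
        days = np.asarray(X, dtype=float).ravel().astype(int)
        y = np.asarray(y, dtype=float).ravel()
        if days.size != y.size or days.size == 0:
            raise ConfigError("X and y must be non-empty and equal length")
        n_days = int(days.max())
        base = self.base_params or ModelParameters.full_fit()
        proto = build_exp2(n_days=n_days)

        ds_lo, ds_hi = map(float, self.d_sleep_range)
        dw_lo, dw_hi = map(float, self.d_wake_range)
        lam_lo, lam_hi = map(float, self.lambda_range)
        if not (ds_hi > ds_lo and dw_hi > dw_lo and lam_hi > lam_lo):
            raise ConfigError("degenerate grid range")
        if self.n_points < 3:
            raise ConfigError("n_points must be >= 3")
        # gaps below ~2 nM produce runaway threshold chatter (hundreds of
        # sub-minute bouts per night, all merged away by scoring anyway)
        ranges = {
            "lambda_": [lam_lo, lam_hi],
            "mid": [0.5 * (ds_lo + dw_lo), 0.5 * (ds_hi + dw_hi)],
            "gap": [max(ds_lo - dw_hi, 2.0), ds_hi - dw_lo],
        }

        init_cache: Dict[float, SystemState] = {}
        sse_cache: Dict[Tuple[float, float, float], float] = {}
        n_evals = 0

        def init_for(lam: float) -> SystemState:
            if lam not in init_cache:
                p = base.replace(lambda_=lam)
                init_cache[lam] = limit_cycle(proto.init_day, p, dt=self.dt)
            return init_cache[lam]

        def sse_at(lam: float, mid: float, gap: float) -> float:
            nonlocal n_evals
            key = (round(lam, 9), round(mid, 9), round(gap, 9))
            if key in sse_cache:
                return sse_cache[key]
            ds, dw = mid + 0.5 * gap, mid - 0.5 * gap
            p = base.replace(lambda_=lam, D_sleep=ds, D_wake=dw)
            init = init_for(lam)
            start = SystemState(proto.schedule.start, init.A_tot,
                                init.R1_tot, init.vigilance)
            _, bouts = run_schedule_bouts(proto.schedule, p, start,
                                          dt=self.dt)
            durs = dict(daily_sleep_durations(bouts, n_days=n_days))
            pred = np.array([durs[d] for d in days])
            val = float(np.sum((pred - y) ** 2))
            sse_cache[key] = val
            n_evals += 1
            return val

        def targets(center: dict) -> Dict[str, float]:
            # resolve D_sleep and D_wake to sig_figs: split the allowance
            # between the midpoint and the gap
            t_thr = self._target_spacing(center["mid"], self.sig_figs)
            return {
                "lambda_": self._target_spacing(center["lambda_"],
                                                self.sig_figs),
                "mid": 0.5 * t_thr,
                "gap": t_thr,
            }

        # Decimal-aligned, digit-by-digit refinement.  The duration
        # objective is piecewise smooth with bout-structure knife edges, so
        # grids are aligned to round decimal values (the resolution the
        # procedure certifies) rather than arbitrary subdivisions, and the
        # two thresholds are profiled out at each candidate lambda before
        # lambda itself is refined.
        MID_STEPS = (2.0, 0.5, 0.1, 0.05)
        GAP_STEPS = (2.0, 0.5, 0.1)
        LAM_STEPS = (10.0, 1.0)

        def aligned_axis(lo: float, hi: float, step: float) -> np.ndarray:
            start = math.ceil(lo / step - 1e-9) * step
            vals = np.arange(start, hi + 1e-9, step)
            if vals.size == 0:
                vals = np.array([0.5 * (lo + hi)])
            return np.round(vals, 10)

        def refine_thresholds(lam: float, mid_win, gap_win):
            """Digit-by-digit aligned grid descent over (mid, gap) at
            fixed lambda; returns (sse, mid, gap)."""
            best = None  # (sse, mid, gap)
            n_levels = max(len(MID_STEPS), len(GAP_STEPS))
            m_win, g_win = list(mid_win), list(gap_win)
            for k in range(n_levels):
                ms = MID_STEPS[min(k, len(MID_STEPS) - 1)]
                gs = GAP_STEPS[min(k, len(GAP_STEPS) - 1)]
                mid_axis = (aligned_axis(m_win[0], m_win[1], ms)
                            if k < len(MID_STEPS) else
                            np.array([best[1]]))
                gap_axis = (aligned_axis(g_win[0], g_win[1], gs)
                            if k < len(GAP_STEPS) else
                            np.array([best[2]]))
                best = None
                for mid in mid_axis:
                    for gap in gap_axis:
                        if gap <= 0.0:
                            continue
                        val = sse_at(lam, float(mid), float(gap))
                        if best is None or val < best[0]:
                            best = (val, float(mid), float(gap))
                # retain more than one step around the incumbent: grid
                # estimates are noisy near bout-structure edges, so keep
                # the neighbouring cells in play
                m_win = [max(best[1] - 1.5 * ms, ranges["mid"][0]),
                         min(best[1] + 1.5 * ms, ranges["mid"][1])]
                g_win = [max(best[2] - 1.5 * gs, ranges["gap"][0]),
                         min(best[2] + 1.5 * gs, ranges["gap"][1])]
            return best

        # Phase 1: anchor survey.  The surface is multimodal across
        # bout-structure regimes organized by the hysteresis gap, so at a
        # few anchor lambdas the thresholds are refined within every gap
        # band; the winning basin seeds the local profiling that follows.
        gap_lo, gap_hi = ranges["gap"]
        edges = list(np.arange(gap_lo, gap_hi, self.gap_band)) + [gap_hi]
        bands = [(float(lo), float(hi))
                 for lo, hi in zip(edges[:-1], edges[1:])]
        anchor_axis = np.round(np.linspace(ranges["lambda_"][0],
                                           ranges["lambda_"][1], 5) / 10.0
                               ) * 10.0
        anchor_best = None  # (sse, lam, mid, gap)
        for lam in anchor_axis:
            for band in bands:
                cand = refine_thresholds(float(lam), ranges["mid"], band)
                if anchor_best is None or cand[0] < anchor_best[0]:
                    anchor_best = (cand[0], float(lam), cand[1], cand[2])

        seed_mid, seed_gap = anchor_best[2], anchor_best[3]
        local_mid = (max(seed_mid - 2.0, ranges["mid"][0]),
                     min(seed_mid + 2.0, ranges["mid"][1]))
        local_gap = (max(seed_gap - 2.0, ranges["gap"][0]),
                     min(seed_gap + 2.0, ranges["gap"][1]))

        profile_cache: Dict[float, tuple] = {}

        def profile(lam: float) -> tuple:
            """(sse, mid, gap) with thresholds refined near the winning
            basin (the global anchor winner is an upper bound)."""
            key = round(lam, 9)
            if key not in profile_cache:
                profile_cache[key] = refine_thresholds(lam, local_mid,
                                                       local_gap)
            return profile_cache[key]

        # Phases 2+: profile lambda on successively finer aligned grids.
        report: List[dict] = []
        lam_win = list(ranges["lambda_"])
        best_lam = None  # (sse, lam)
        for level, ls in enumerate(LAM_STEPS):
            lam_axis = aligned_axis(lam_win[0], lam_win[1], ls)
            best_lam = None
            for lam in lam_axis:
                s = profile(float(lam))[0]
                if best_lam is None or s < best_lam[0]:
                    best_lam = (s, float(lam))
            report.append({
                "level": level,
                "lambda_step": ls,
                "lambda_axis": [float(v) for v in lam_axis],
                "profiled_sse": [profile(float(v))[0] for v in lam_axis],
                "best": {"lambda_": best_lam[1], "sse": best_lam[0]},
            })
            lam_win = [max(best_lam[1] - 1.5 * ls, ranges["lambda_"][0]),
                       min(best_lam[1] + 1.5 * ls, ranges["lambda_"][1])]

        sse, mid, gap = profile(best_lam[1])
        if anchor_best[0] < sse:
            # the anchor survey found a better basin than the profiled one
            sse, mid, gap = anchor_best[0], anchor_best[2], anchor_best[3]
            best_lam = (sse, anchor_best[1])
        self.lambda_ = best_lam[1]
        self.d_sleep_ = mid + 0.5 * gap
        self.d_wake_ = mid - 0.5 * gap
        self.sse_ = sse
        self.spacing_ = {
            "lambda_": LAM_STEPS[-1],
            "D_sleep": MID_STEPS[-1] + 0.5 * GAP_STEPS[-1],
            "D_wake": MID_STEPS[-1] + 0.5 * GAP_STEPS[-1],
        }
        self.grid_report_ = report
        self.n_evals_ = n_evals
        self.params_ = base.replace(lambda_=self.lambda_,
                                    D_sleep=self.d_sleep_,
                                    D_wake=self.d_wake_)
        self._proto_days = n_days
        return self

    def predict(self, X) -> np.ndarray:
        days = np.asarray(X, dtype=float).ravel().astype(int)
        n_days = int(days.max())
        proto = build_exp2(n_days=n_days)
        init = limit_cycle(proto.init_day, self.params_, dt=self.dt)
        start = SystemState(proto.schedule.start, init.A_tot, init.R1_tot,
                            init.vigilance)
        traj = simulate_schedule(proto.schedule, self.params_, start,
                                 dt=self.dt)
        durs = dict(daily_sleep_durations(traj.bouts, n_days=n_days))
        return np.array([durs[d] for d in days])


class SigmoidRecalibrationEstimator(BaseEstimator):
    """Two-parameter LM refit of the performance sigmoid (D_mid, D_s).

    The sleep drive trajectory is independent of the sigmoid, so it is
    computed once at the base parameters and the refit reduces to a
    two-parameter logistic regression on the sampled drives.  Sleep/wake
    outputs are untouched by construction.
    """

    def __init__(self, base_params: Optional[ModelParameters] = None,
                 dt: float = FIT_DT, max_nfev: int = 200):
        self.base_params = base_params
        self.dt = dt
        self.max_nfev = max_nfev

    def fit(self, X: pd.DataFrame, y):
        obs = pd.DataFrame({
            "condition": np.asarray(X["condition"]),
            "time_h": np.asarray(X["time_h"], dtype=float),
            "value": np.asarray(y, dtype=float),
        })
        base = self.base_params or ModelParameters.full_fit()
        protos = _protocols_for(sorted(obs["condition"].unique()))
        times_by_cond = _align_times(obs, protos)
        first = next(iter(protos.values()))
        init = limit_cycle(first.init_day, base, dt=self.dt)
        drives: List[np.ndarray] = []
        targets: List[np.ndarray] = []
        for cond in sorted(times_by_cond):
            proto = protos[cond]
            start = SystemState(proto.schedule.start, init.A_tot,
                                init.R1_tot, init.vigilance)
            t = times_by_cond[cond]
            A, R = states_at_times(proto.schedule, base, t, start, dt=self.dt)
            R1b = binding_equilibrium(A, R, base).R1_b
            drives.append(sleep_drive(R1b, t, base))
            grp = obs[obs["condition"] == cond].sort_values("time_h")
            targets.append(np.asarray(grp["value"], dtype=float))
        D = np.concatenate(drives)
        y_all = np.concatenate(targets)

        def residuals(z):
            d_mid, d_s = z[0], math.exp(z[1])
            return base.p_max * expit((D - d_mid) / d_s) - y_all

        z0 = np.array([base.D_mid, math.log(base.D_s)])
        res = least_squares(residuals, z0, method="lm",
                            max_nfev=self.max_nfev, xtol=1e-12, ftol=1e-12)
        self.d_mid_ = float(res.x[0])
        self.d_s_ = float(math.exp(res.x[1]))
        self.params_ = base.replace(D_mid=self.d_mid_, D_s=self.d_s_)
        pred = y_all + res.fun
        sse = float(np.sum(res.fun ** 2))
        self.sse_ = sse
        self.result_ = FitResult(
            parameters=self.params_, sse=sse,
            adjusted_r2=adjusted_r2(y_all, pred, 2),
            rmse=rmse(y_all, pred), n_obs=int(y_all.size), n_params=2,
            converged=bool(res.status > 0), n_iterations=int(res.nfev),
            message=str(res.message),
        )
        self._drives = D
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        obs = pd.DataFrame({
            "condition": np.asarray(X["condition"]),
            "time_h": np.asarray(X["time_h"], dtype=float),
            "value": 0.0,
        })
        protos = _protocols_for(sorted(obs["condition"].unique()))
        times_by_cond = _align_times(obs, protos)
        preds = _predict_pvt(self.params_, protos, times_by_cond, self.dt)
        out = []
        for cond in sorted(times_by_cond):
            out.append(preds[cond])
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_stage1(observations: pd.DataFrame, **kwargs) -> FitResult:
    """Stage-1 LM fit; ``observations`` has columns condition/time_h/value."""
    obs = _check_observations(observations)
    est = PVTStage1Estimator(**kwargs)
    est.fit(obs[["condition", "time_h"]], obs["value"])
    return est.result_


def fit_stage2(durations: pd.DataFrame, **kwargs,
               ) -> Tuple[float, float, float]:
    """Stage-2 grid search; ``durations`` has columns day/value.

    Returns the SSE-minimizing (lambda, D_sleep, D_wake) triple; the full
    grid evaluation is available on the estimator
    (:class:`SleepTimingStage2Estimator`) for diagnostics.
    """
    if not {"day", "value"}.issubset(durations.columns):
        raise ConfigError("durations need columns ['day', 'value']")
    est = SleepTimingStage2Estimator(**kwargs)
    est.fit(durations["day"], durations["value"])
    return est.lambda_, est.d_sleep_, est.d_wake_


def fit_stage3_recalibrate(observations: pd.DataFrame, **kwargs,
                           ) -> Tuple[float, float]:
    """Stage-3 sigmoid recalibration; returns the refit (D_mid, D_s)."""
    obs = _check_observations(observations)
    est = SigmoidRecalibrationEstimator(**kwargs)
    est.fit(obs[["condition", "time_h"]], obs["value"])
    return est.d_mid_, est.d_s_
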