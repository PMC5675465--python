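"""Synthetic observation series with known generating parameters.

The group-average observation series the model was originally calibrated
against are not redistributable, so parameter estimation is exercised on
synthetic data: the named protocol is simulated at known parameters and
i.i.d. Gaussian noise is added to the observable (truncated to its
physical range).  A metadata sidecar records the generating truth so
recovery tests can close the loop.  The noise model is a test convention
(the originals are group means), not a claim about measurement error.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import daily_sleep_durations
from .errors import ConfigError
from .fitting import FIT_DT, _predict_pvt, _protocols_for
from .params import ModelParameters
from .protocol import EXP1_CONDITIONS, build_exp2, pvt_sample_times
from .simulate import simulate_protocol

__all__ = ["make_pvt_exp1", "make_sleep_exp2", "make_fixtures",
           "DEFAULT_PVT_NOISE_SD"]

#: Default observation noise on lapse counts (lapses).
DEFAULT_PVT_NOISE_SD = 2.0


def make_pvt_exp1(params: Optional[ModelParameters] = None,
                  noise_sd: float = DEFAULT_PVT_NOISE_SD, seed: int = 0,
                  dt: float = FIT_DT,
                  conditions: Sequence[str] = tuple(EXP1_CONDITIONS),
                  ) -> pd.DataFrame:
    """Noisy PVT lapse observations for the forced-schedule conditions.

    Columns: ``condition``, ``time_h``, ``value``.  Times are the
    protocol's PVT sampling grid from the start of the condition; values
    are model predictions plus truncated Gaussian noise.
    """
    params = params or ModelParameters.pvt_fit()
    rng = np.random.default_rng(seed)
    protos = _protocols_for(sorted(conditions))
    times_by_cond = {
        c: pvt_sample_times(p.schedule, start=p.t_condition_start)
        for c, p in protos.items()
    }
    preds = _predict_pvt(params, protos, times_by_cond, dt)
    frames = []
    for cond in sorted(protos):
        values = preds[cond].copy()
        if noise_sd > 0.0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        values = np.clip(values, 0.0, params.p_max)
        frames.append(pd.DataFrame({
            "condition": cond,
            "time_h": times_by_cond[cond],
            "value": values,
        }))
    return pd.concat(frames, ignore_index=True)


def make_sleep_exp2(params: Optional[ModelParameters] = None,
                    noise_sd: float = 0.0, seed: int = 0,
                    dt: float = FIT_DT, n_days: int = 28) -> pd.DataFrame:
    """Daily total sleep durations from the simulated long-night protocol.

    Columns: ``day`` (1-based night number), ``value`` (hours, in
    [0, 14]).
    """
    params = params or ModelParameters.full_fit()
    rng = np.random.default_rng(seed)
    proto = build_exp2(n_days=n_days)
    traj = simulate_protocol(proto, params, dt=dt)
    pairs = daily_sleep_durations(traj.bouts, n_days=n_days)
    days = np.array([d for d, _ in pairs], dtype=int)
    values = np.array([v for _, v in pairs], dtype=float)
    if noise_sd > 0.0:
        values = np.clip(values + rng.normal(0.0, noise_sd, size=values.shape),
                         0.0, 14.0)
    return pd.DataFrame({"day": days, "value": values})


def make_fixtures(kind: str, out_dir, params: Optional[ModelParameters] = None,
                  noise_sd: Optional[float] = None, seed: int = 0,
                  dt: float = FIT_DT) -> Dict[str, Path]:
    """Write a fixture CSV plus a truth-metadata sidecar; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "pvt_exp1":
        params = params or ModelParameters.pvt_fit()
        sd = DEFAULT_PVT_NOISE_SD if noise_sd is None else noise_sd
        df = make_pvt_exp1(params=params, noise_sd=sd, seed=seed, dt=dt)
    elif kind == "sleep_exp2":
        params = params or ModelParameters.full_fit()
        sd = 0.0 if noise_sd is None else noise_sd
        df = make_sleep_exp2(params=params, noise_sd=sd, seed=seed, dt=dt)
    else:
        raise ConfigError(
            f"unknown fixture kind {kind!r}; "
            "choose 'pvt_exp1' or 'sleep_exp2'"
        )
    csv_path = out_dir / f"{kind}.csv"
    meta_path = out_dir / f"{kind}.truth.json"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "kind": kind,
        "noise_sd": sd,
        "seed": seed,
        "dt": dt,
        "generating_parameters": params.to_dict(),
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return {"data": csv_path, "truth": meta_path}
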