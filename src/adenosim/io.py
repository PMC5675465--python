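"""Run configuration and serialization.

Interchange formats are deliberately plain: CSV with header rows and
times as floating-point hours (written at 17 significant digits so
round-trips are exact), YAML or JSON accepted interchangeably for
configuration.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml

from .analytics import equilibrium_receptor_total, typical_atot_coefficients
from .core import SLEEP, WAKE, SystemState
from .errors import ConfigError
from .params import ModelParameters
from .protocol import (FORCED_WAKE, ProtocolSpec, Schedule,
                       _protocol_preset)

__all__ = ["RunConfig", "load_config", "write_trajectory", "write_bouts",
           "write_durations", "raster_text"]

_FLOAT_FMT = "%.17g"

_CONFIG_KEYS = {"parameters", "protocol", "dt", "out_dir", "seed"}


@dataclass
class RunConfig:
    """Validated simulation run configuration.

    ``parameters`` overrides individual model parameters on top of the
    full-fit defaults; ``protocol`` is a preset name (``exp2``,
    ``exp1:tib4``, ...) or an inline list of ``{start, end, mode}``
    segments; ``dt`` the integration step in hours.
    """

    parameters: Dict[str, float] = field(default_factory=dict)
    protocol: Union[str, List[dict]] = "exp2"
    dt: float = 0.01
    out_dir: str = "adenosim_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ConfigError(f"dt must be > 0, got {self.dt!r}")
        try:
            self.model_parameters()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid parameter overrides: {exc}") from exc

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def model_parameters(self) -> ModelParameters:
        try:
            return ModelParameters.full_fit().replace(**self.parameters)
        except TypeError as exc:
            raise ConfigError(f"unknown model parameter: {exc}") from exc

    def protocol_spec(self) -> ProtocolSpec:
        if isinstance(self.protocol, str):
            return _protocol_preset(self.protocol)
        sched = Schedule.from_records(self.protocol)
        return ProtocolSpec(name="custom", schedule=sched,
                            init_day=_default_init_day(), t_condition_start=sched.start)

    def initial_state(self, params: ModelParameters) -> Optional[SystemState]:
        """Explicit initial state for inline schedules (presets use their
        own limit-cycle recipe and return None here)."""
        if isinstance(self.protocol, str):
            return None
        sched = Schedule.from_records(self.protocol)
        c_w, c_s = typical_atot_coefficients(
            8.0, params.chi_wake, params.chi_sleep)
        A0 = c_w * params.mu_wake + c_s * params.mu_sleep
        R0 = equilibrium_receptor_total(A0, params)
        vig = WAKE if sched.segments[0].mode == FORCED_WAKE else SLEEP
        return SystemState(sched.start, A0, R0, vig)


def _default_init_day() -> Schedule:
    from .protocol import regular_day
    return regular_day(8.0, wake_time=8.0)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"could not parse config {path}: {exc}") from exc
    return RunConfig.from_dict(data or {})


def write_trajectory(traj, path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_bouts(traj, path) -> Path:
    path = Path(path)
    traj.bouts_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_durations(pairs, path) -> Path:
    path = Path(path)
    pd.DataFrame(pairs, columns=["day", "value"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)
    return path


def raster_text(bouts, n_days: Optional[int] = None, res: float = 0.5,
                double_plot: bool = True) -> str:
    """Double-plotted raster of sleep timing as a text grid.

    One row per day starting at midnight; ``#`` marks sleep, ``.`` wake;
    with ``double_plot`` each row spans 48 h so episodes crossing midnight
    read continuously.
    """
    if n_days is None:
        n_days = 1 if not bouts else int(math.ceil(
            max(b.offset for b in bouts) / 24.0))
    span = 48.0 if double_plot else 24.0
    n_cols = int(round(span / res))
    rows = []
    for day in range(n_days):
        t0 = 24.0 * day
        cells = []
        for c in range(n_cols):
            lo = t0 + c * res
            hi = lo + res
            asleep = any(b.onset < hi and b.offset > lo for b in bouts)
            cells.append("#" if asleep else ".")
        rows.append("".join(cells))
    return "\n".join(rows) + "\n"
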