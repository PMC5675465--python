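"""Model parameters for the adenosine receptor-ligand sleep model.

All concentrations are in nM and all times in hours, everywhere in the
package; there is no unit-conversion layer.  The circadian angular
frequency ``omega = 2*pi/24 h^-1`` is a fixed constant, not a parameter.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

__all__ = ["OMEGA", "ModelParameters"]

#: Circadian angular frequency (h^-1); the circadian process has a fixed 24 h period.
OMEGA: float = 2.0 * math.pi / 24.0


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, concentrations, circadian and performance parameters.

    Defaults are the full fit of the model: the adenosine/receptor
    parameters were calibrated against group-average PVT lapses under acute
    sleep deprivation and chronic sleep restriction, the receptor time
    constant and the two sleep/wake thresholds against daily sleep
    durations in a long-sleep-opportunity protocol, and the performance
    sigmoid then recalibrated.

    Parameters
    ----------
    Kd1, Kd2:
        Dissociation constants of the A1 and A2A receptors (nM).  A1 binds
        adenosine with ~100x higher affinity than A2A.
    chi_wake, chi_sleep:
        Time constants of total-adenosine relaxation in wake and sleep (h).
    mu_wake, mu_sleep:
        Saturation concentrations of total adenosine in wake and sleep (nM);
        ``mu_wake > mu_sleep > 0``.
    lambda_:
        Time constant of A1-receptor up/down-regulation (h); large, so
        receptor pools respond on a timescale of weeks.
    gamma:
        Homeostatic target A1 occupancy fraction, ``0 < gamma < 1``.
    R2_tot:
        Total A2A receptor concentration (nM); fixed, not regulated.
    a, phi:
        Circadian amplitude (nM) and clock time (h, mod 24, 0 = midnight)
        of maximal circadian sleep promotion.
    p_max, D_mid, D_s:
        PVT lapse ceiling, sleep drive at half-maximal lapses (nM), and
        sigmoid width (nM).
    D_sleep, D_wake:
        Hysteresis thresholds on the sleep drive for spontaneous sleep
        onset and wake onset (nM); ``D_wake < D_sleep``.
    """

    Kd1: float = 1.0
    Kd2: float = 100.0
    chi_wake: float = 18.18
    chi_sleep: float = 4.20
    mu_wake: float = 869.5
    mu_sleep: float = 596.4
    lambda_: float = 291.0
    gamma: float = 0.9677
    R2_tot: float = 300.0
    a: float = 3.25
    phi: float = 7.95
    p_max: float = 60.0
    D_mid: float = 583.2
    D_s: float = 5.872
    D_sleep: float = 572.7
    D_wake: float = 555.4

    def __post_init__(self) -> None:
        positive = [
            "Kd1", "Kd2", "chi_wake", "chi_sleep", "mu_wake", "mu_sleep",
            "lambda_", "R2_tot", "p_max", "D_s",
        ]
        for name in positive:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.a < 0.0:
            raise ValueError(f"circadian amplitude a must be >= 0, got {self.a!r}")
        if not 0.0 <= self.phi < 24.0:
            raise ValueError(f"phi must lie in [0, 24), got {self.phi!r}")
        if not self.mu_wake > self.mu_sleep:
            raise ValueError(
                f"mu_wake ({self.mu_wake}) must exceed mu_sleep ({self.mu_sleep})"
            )
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma!r}")
        if not self.D_wake < self.D_sleep:
            raise ValueError(
                f"hysteresis requires D_wake ({self.D_wake}) < D_sleep ({self.D_sleep})"
            )

    @property
    def beta(self) -> float:
        """Fraction of free adenosine steered to A2A receptors at equilibrium.

        ``beta = R2_u / (R2_u + Kd2)`` with the unbound A2A pool held at its
        total value (A2A affinity is low compared with physiological free
        adenosine, so A2A receptors are mostly unoccupied).
        """
        return self.R2_tot / (self.R2_tot + self.Kd2)

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def full_fit(cls) -> "ModelParameters":
        """The final calibrated parameter set (the class defaults)."""
        return cls()

    @classmethod
    def pvt_fit(cls) -> "ModelParameters":
        """The PVT-only calibration (before the sleep-timing stage).

        Differs from the full fit in the nominal receptor time constant
        (300 h) and the performance sigmoid (D_mid = 579.3 nM,
        D_s = 5.603 nM).  The sleep/wake thresholds play no role in
        forced-schedule protocols; they keep their full-fit values here so
        the parameter set remains valid.
        """
        return cls(lambda_=300.0, D_mid=579.3, D_s=5.603)
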