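"""Linear-quadratic radiobiology: survival, incomplete repair, fractionation.

The LQ model writes the log cell kill of an acute dose D (Gy) as

    -ln(S) = alpha*D + beta*D**2

with the alpha/beta ratio (Gy) controlling the bendiness of the survival
curve.  For protracted exposure of duration t the quadratic term is
attenuated by the incomplete-repair factor

    g(t) = 2*(mu*t - 1 + exp(-mu*t)) / (mu*t)**2,   mu = ln(2)/T_half,

which decays from 1 (instantaneous delivery) toward 0 as sublethal damage
is repaired during the exposure.  T_half is the recovery half-time in
hours and all exposure durations are converted to hours before forming
mu*t.

The module also provides the fractionated input form

    u_r = a0 + a1*D + a2*D*d + a3*D*d**2 + ...

as an evaluator over user-supplied coefficients, and the daily RT drive:
protocols are specified as Gy per calendar day, delivered as a constant
rate over the dosing day, so the drive for day k is simply the Gy total of
that day interpreted as Gy/day.  Downstream normalization by C50_r
(Gy/day) absorbs the Gy -> model-unit conversion, so no explicit
conversion constant is introduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .schedules import Channel, DoseSchedule

__all__ = [
    "LQParameters",
    "FractionationScheme",
    "default_lq_parameters",
    "lq_log_kill",
    "repair_factor",
    "incomplete_repair_effect",
    "fractionated_input",
    "daily_rt_drive",
    "incomplete_repair_weighted_schedule",
]

# below this mu*t the closed form of g loses precision to cancellation;
# switch to its Taylor series
_SERIES_THRESHOLD = 1e-6


@dataclass(frozen=True)
class LQParameters:
    """LQ coefficients: alpha (1/Gy), beta (1/Gy**2), T_half (hours)."""

    alpha: float
    beta: float
    T_half: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError("alpha: must be > 0")
        if self.beta <= 0:
            raise ValidationError("beta: must be > 0")
        if self.T_half <= 0:
            raise ValidationError("T_half: must be > 0")

    @property
    def alpha_over_beta(self) -> float:
        """The alpha/beta ratio in Gy."""
        return self.alpha / self.beta

    @property
    def mu(self) -> float:
        """Repair rate ln(2)/T_half, 1/hour."""
        return math.log(2.0) / self.T_half

    @classmethod
    def from_ratio(
        cls, alpha: float, alpha_over_beta: float, T_half: float = 1.0
    ) -> "LQParameters":
        """Build from alpha and the alpha/beta ratio."""
        return cls(alpha=alpha, beta=alpha / alpha_over_beta, T_half=T_half)


def default_lq_parameters() -> LQParameters:
    """alpha/beta = 10 Gy with alpha = 0.3/Gy, T_half = 1 h."""
    return LQParameters.from_ratio(alpha=0.3, alpha_over_beta=10.0, T_half=1.0)


def lq_log_kill(D: float, lq: LQParameters) -> float:
    """-ln(survival) = alpha*D + beta*D**2 for an acute dose D in Gy."""
    if D < 0:
        raise ValueError("dose must be >= 0")
    return lq.alpha * D + lq.beta * D * D


def repair_factor(t_hours: float, lq: LQParameters) -> float:
    """Incomplete-repair g-factor for an exposure lasting ``t_hours``.

    g = 2*(mu*t - 1 + exp(-mu*t)) / (mu*t)**2, evaluated by Taylor series
    for mu*t below 1e-6; g -> 1 as the exposure becomes instantaneous.
    """
    if t_hours < 0:
        raise ValueError("exposure duration must be >= 0")
    x = lq.mu * t_hours
    if x < _SERIES_THRESHOLD:
        # 2*(x - 1 + e^-x)/x^2 = 1 - x/3 + x^2/12 - x^3/60 + ...
        return 1.0 - x / 3.0 + x * x / 12.0 - x ** 3 / 60.0
    return 2.0 * (x - 1.0 + math.exp(-x)) / (x * x)


def incomplete_repair_effect(D: float, t_hours: float, lq: LQParameters) -> float:
    """Level of effect alpha*D + beta*D**2*g(t) for protracted exposure."""
    if D < 0:
        raise ValueError("dose must be >= 0")
    return lq.alpha * D + lq.beta * D * D * repair_factor(t_hours, lq)


@dataclass(frozen=True)
class FractionationScheme:
    """Total dose D split into fractions of d Gy with input coefficients a_i."""

    D: float
    d: float
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValidationError("d: dose per fraction must be > 0")
        if self.D < self.d:
            raise ValidationError("D: total dose must be >= dose per fraction")

    @property
    def n_fractions(self) -> float:
        return self.D / self.d

    def input_rate(self) -> float:
        return fractionated_input(self.coefficients, self.D, self.d)


def fractionated_input(coefficients: Sequence[float], D: float, d: float) -> float:
    """Evaluate u_r = a0 + a1*D + a2*D*d + a3*D*d**2 + ...

    The coefficients are never tabulated in the source model and protocols
    are specified directly in Gy per day, so this evaluator is provided
    for user-supplied coefficient sets and is not part of the default
    pipeline.
    """
    if not coefficients:
        return 0.0
    total = coefficients[0]
    power = 1.0
    for a_i in coefficients[1:]:
        total += a_i * D * power
        power *= d
    return total


def daily_rt_drive(schedule: DoseSchedule, day: int) -> float:
    """Gy delivered on a 1-based calendar day, as a constant Gy/day rate."""
    if schedule.channel is not Channel.RT:
        raise ValidationError(
            f"channel: daily_rt_drive needs an RT schedule, got {schedule.channel.value}"
        )
    return schedule.amount_on(day)


def incomplete_repair_weighted_schedule(
    schedule: DoseSchedule, lq: LQParameters, exposure_hours: float
) -> DoseSchedule:
    """Re-weight each fraction by its incomplete-repair effect (optional).

    Each daily dose D is replaced by the alpha-equivalent dose
    E/alpha = D + (beta/alpha)*D**2*g(t), a BED-style weighting that
    credits the quadratic kill of large fractions.  Off by default: the
    plain physical Gy per day drives the model unless the caller opts in.
    """
    if schedule.channel is not Channel.RT:
        raise ValidationError(
            f"channel: weighting applies to RT schedules, got {schedule.channel.value}"
        )
    weighted = [
        (event.day, incomplete_repair_effect(event.amount, exposure_hours, lq) / lq.alpha)
        for event in schedule.events
    ]
    return DoseSchedule.from_pairs(
        Channel.RT, weighted, horizon=schedule.horizon, mode=schedule.mode
    )
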