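"""ODE right-hand sides and the fixed-step integrator.

Combined model states
---------------------
x1   proliferating tumor volume, mm³
x2   necrotic tumor volume, mm³
x3   AG serum level, mg/mL          xe3  AG effect-site level, mg/mL
x4   IM serum level, mg/mL          xe4  IM effect-site level, mg/mL
x5   RT drive level, Gy/day-equiv.  xe5  RT effect-site level, Gy/day-equiv.

Dynamics:

    dx1  = (a - n)*x1 - E*x1          dx2  = n*x1 + E*x1
    dx3  = -c_a*x3 + u_a(t)           dxe3 = -c_a*xe3 + Et_a*x3
    dx4  = -c_i*x4 + u_i(t)           dxe4 = -c_i*xe4 + Et_i*x4
    dx5  = -c_r*x5 + u_r(t)           dxe5 = -c_r*xe5 + Et_r*x5

where Et_a, Et_i, Et_r and the combined kill E are the Hill-surface terms
evaluated from the instantaneous state (plain nonlinear coupling, not an
algebraic loop) and E is scaled by ``unit_rate``.  The kill flux moves
proliferating volume into the necrotic compartment, so total volume obeys
d(x1+x2)/dt = a*x1 exactly.

Integration is fixed-step classical Runge–Kutta (RK4) with steps aligned
to the day boundaries where the piecewise-constant inputs jump, making
repeated runs bit-for-bit identical.  The legacy Bevacizumab-only model
(Michaelis–Menten inhibitor clearance, saturable inhibition) is provided
alongside for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrationError, ValidationError
from .parameters import CombinedParameters, LegacyAGParameters
from .schedules import Channel, DoseSchedule, rate_function
from .surfaces import EffectBreakdown, combined_effect

__all__ = [
    "StateVector",
    "Trajectory",
    "LegacyTrajectory",
    "combined_rhs",
    "legacy_rhs",
    "simulate",
    "simulate_legacy",
]

logger = logging.getLogger(__name__)

_EFFECT_COLUMNS = (
    "Et_a", "Et_i", "Et_r", "E_ai", "E_ar", "E_ir", "Et_all", "Ed_all", "E",
)


class StateVector(NamedTuple):
    """The eight combined-model states, all nonnegative along trajectories."""

    x1: float
    x2: float
    x3: float
    xe3: float
    x4: float
    xe4: float
    x5: float
    xe5: float


@dataclass(frozen=True)
class Trajectory:
    """Daily-sampled solution of the combined model.

    ``states`` has one row per output time and the eight StateVector
    columns; ``effects`` carries the effect breakdown re-evaluated at each
    output state (columns Et_a..E).
    """

    times: np.ndarray
    states: np.ndarray
    effects: np.ndarray = field(repr=False)

    @property
    def total_volume(self) -> np.ndarray:
        """x1 + x2 per output time, mm³."""
        return self.states[:, 0] + self.states[:, 1]

    def state_at(self, index: int) -> StateVector:
        return StateVector(*self.states[index])

    def effect_at(self, index: int) -> EffectBreakdown:
        return EffectBreakdown(*self.effects[index])

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with the canonical trajectory column schema."""
        frame = pd.DataFrame(
            {
                "time_day": self.times,
                "x1_mm3": self.states[:, 0],
                "x2_mm3": self.states[:, 1],
                "total_mm3": self.total_volume,
                "x3": self.states[:, 2],
                "xe3": self.states[:, 3],
                "x4": self.states[:, 4],
                "xe4": self.states[:, 5],
                "x5": self.states[:, 6],
                "xe5": self.states[:, 7],
            }
        )
        frame["E"] = self.effects[:, 8]
        frame["Et_a"] = self.effects[:, 0]
        frame["Et_i"] = self.effects[:, 1]
        frame["Et_r"] = self.effects[:, 2]
        return frame


@dataclass(frozen=True)
class LegacyTrajectory:
    """Daily-sampled solution of the Bevacizumab-only model (x1, x2, x3)."""

    times: np.ndarray
    states: np.ndarray

    @property
    def total_volume(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]


_warned_labels: set[str] = set()


def _clip_negative(y: Sequence[float], label: str) -> tuple[float, ...]:
    if min(y) < 0.0:
        if label not in _warned_labels:  # one warning per run, not per step
            logger.warning("%s: negative state component clipped to 0", label)
            _warned_labels.add(label)
        return tuple(max(v, 0.0) for v in y)
    return tuple(y)


def _combined_derivative(
    y: tuple[float, ...],
    p: CombinedParameters,
    u_a: float,
    u_i: float,
    u_r: float,
) -> tuple[float, ...]:
    """Float-tuple RHS fast path shared by the integrator and the API."""
    y = _clip_negative(y, "combined model")
    x1, x2, x3, xe3, x4, xe4, x5, xe5 = y
    eff = combined_effect(y, p, inputs=(u_a, u_i, u_r))
    kill = eff.E * p.unit_rate
    return (
        (p.a - p.n) * x1 - kill * x1,
        p.n * x1 + kill * x1,
        -p.c_a * x3 + u_a,
        -p.c_a * xe3 + eff.Et_a * x3,
        -p.c_i * x4 + u_i,
        -p.c_i * xe4 + eff.Et_i * x4,
        -p.c_r * x5 + u_r,
        -p.c_r * xe5 + eff.Et_r * x5,
    )


def combined_rhs(
    t: float,
    state: Sequence[float],
    params: CombinedParameters,
    schedules: Mapping[Channel, DoseSchedule],
) -> StateVector:
    """Time derivative of the combined model at (t, state)."""
    rates = {
        channel: rate_function(schedule, t)
        for channel, schedule in schedules.items()
        if schedule.mode == "infusion"
    }
    return StateVector(
        *_combined_derivative(
            tuple(state),
            params,
            rates.get(Channel.AG, 0.0),
            rates.get(Channel.IM, 0.0),
            rates.get(Channel.RT, 0.0),
        )
    )


def legacy_rhs(
    t: float,
    state: Sequence[float],
    params: LegacyAGParameters,
    u_a: float,
) -> tuple[float, float, float]:
    """Time derivative of the Bevacizumab-only model at (t, state).

    dx1 = (a - n_a)*x1 - b_a*x1*x3/(ED50_a + x3)
    dx2 = n_a*x1 + b_a*x1*x3/(ED50_a + x3)
    dx3 = -c_a*x3/(K_Ba + x3) - b_ak*x1*x3/(ED50_a + x3) + u_a
    """
    x1, x2, x3 = _clip_negative(tuple(state), "legacy model")
    saturable = x3 / (params.ED50_a + x3) if x3 > 0.0 else 0.0
    inhibition = params.b_a * x1 * saturable
    return (
        (params.a - params.n_a) * x1 - inhibition,
        params.n_a * x1 + inhibition,
        -params.c_a * x3 / (params.K_Ba + x3) - params.b_ak * x1 * saturable + u_a,
    )


def _steps_per_day(step: float) -> int:
    if not 0.0 < step <= 0.05:
        raise ValidationError("step: must satisfy 0 < step <= 0.05 day")
    nsub = int(round(1.0 / step))
    if nsub < 20:
        raise ValidationError("step: must divide one day into >= 20 substeps")
    return nsub


def _normalize_schedules(
    schedules: Mapping[Channel, DoseSchedule] | Sequence[DoseSchedule] | None,
    horizon: int,
) -> dict[Channel, DoseSchedule]:
    if schedules is None:
        schedules = {}
    if not isinstance(schedules, Mapping):
        schedules = {schedule.channel: schedule for schedule in schedules}
    out: dict[Channel, DoseSchedule] = {}
    for channel in Channel:
        schedule = schedules.get(channel)
        if schedule is None:
            schedule = DoseSchedule.empty(channel, horizon)
        elif schedule.channel is not channel:
            raise ValidationError(
                f"schedules: {schedule.channel.value} schedule mapped to {channel.value}"
            )
        out[channel] = schedule
    return out


def simulate(
    params: CombinedParameters,
    schedules: Mapping[Channel, DoseSchedule] | Sequence[DoseSchedule] | None = None,
    horizon: int = 30,
    step: float = 0.01,
    initial_state: StateVector | None = None,
) -> Trajectory:
    """Integrate the combined model and sample it on the daily grid.

    Starts from (x1, x2, ..) = (V0, 0, ..., 0) unless ``initial_state`` is
    given.  ``schedules`` maps channels to dose schedules; missing
    channels receive no input.  The integrator is fixed-step RK4 with
    ``1/step`` substeps per day (step <= 0.05 day), so identical inputs
    give bit-for-bit identical trajectories.
    """
    if horizon < 1:
        raise ValidationError("horizon: must be >= 1")
    _warned_labels.clear()
    nsub = _steps_per_day(step)
    h = 1.0 / nsub
    sched = _normalize_schedules(schedules, horizon)

    per_day = {ch: s.daily_amounts(horizon) for ch, s in sched.items()}
    infusion = {
        ch: per_day[ch] if sched[ch].mode == "infusion" else [0.0] * horizon
        for ch in Channel
    }
    bolus = {
        ch: per_day[ch] if sched[ch].mode == "bolus" else None for ch in Channel
    }
    has_bolus = any(b is not None for b in bolus.values())
    # serum-state index per channel, for bolus injection
    serum_index = {Channel.AG: 2, Channel.IM: 4, Channel.RT: 6}

    y: tuple[float, ...]
    if initial_state is None:
        y = (params.V0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    else:
        y = tuple(float(v) for v in initial_state)
        if len(y) != 8:
            raise ValidationError("initial_state: expected 8 components")

    times = np.arange(horizon + 1, dtype=float)
    states = np.empty((horizon + 1, 8), dtype=float)
    states[0] = y

    for day in range(horizon):
        if has_bolus:
            y = list(y)
            for ch in Channel:
                amounts = bolus[ch]
                if amounts is not None and amounts[day] > 0.0:
                    y[serum_index[ch]] += amounts[day]
            y = tuple(y)
        u_a = infusion[Channel.AG][day]
        u_i = infusion[Channel.IM][day]
        u_r = infusion[Channel.RT][day]
        for k in range(nsub):
            k1 = _combined_derivative(y, params, u_a, u_i, u_r)
            y2 = tuple(y[i] + 0.5 * h * k1[i] for i in range(8))
            k2 = _combined_derivative(y2, params, u_a, u_i, u_r)
            y3 = tuple(y[i] + 0.5 * h * k2[i] for i in range(8))
            k3 = _combined_derivative(y3, params, u_a, u_i, u_r)
            y4 = tuple(y[i] + h * k3[i] for i in range(8))
            k4 = _combined_derivative(y4, params, u_a, u_i, u_r)
            y = tuple(
                y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                for i in range(8)
            )
            if min(y) < 0.0:
                y = _clip_negative(y, "combined model step")
        if not all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at t={day + 1} day; check parameters and step"
            )
        states[day + 1] = y

    effects = np.empty((horizon + 1, 9), dtype=float)
    for idx in range(horizon + 1):
        effects[idx] = combined_effect(tuple(states[idx]), params).as_tuple()
    return Trajectory(times=times, states=states, effects=effects)


def simulate_legacy(
    params: LegacyAGParameters,
    schedule: DoseSchedule | None = None,
    horizon: int = 30,
    step: float = 0.01,
    initial_state: Sequence[float] = (1000.0, 0.0, 0.0),
) -> LegacyTrajectory:
    """Integrate the Bevacizumab-only model with the same RK4 driver."""
    if horizon < 1:
        raise ValidationError("horizon: must be >= 1")
    _warned_labels.clear()
    nsub = _steps_per_day(step)
    h = 1.0 / nsub
    daily = (
        schedule.daily_amounts(horizon) if schedule is not None else [0.0] * horizon
    )
    y = tuple(float(v) for v in initial_state)
    if len(y) != 3:
        raise ValidationError("initial_state: expected 3 components")
    times = np.arange(horizon + 1, dtype=float)
    states = np.empty((horizon + 1, 3), dtype=float)
    states[0] = y
    for day in range(horizon):
        u_a = daily[day]
        for k in range(nsub):
            t = day + k * h
            k1 = legacy_rhs(t, y, params, u_a)
            y2 = tuple(y[i] + 0.5 * h * k1[i] for i in range(3))
            k2 = legacy_rhs(t + 0.5 * h, y2, params, u_a)
            y3 = tuple(y[i] + 0.5 * h * k2[i] for i in range(3))
            k3 = legacy_rhs(t + 0.5 * h, y3, params, u_a)
            y4 = tuple(y[i] + h * k3[i] for i in range(3))
            k4 = legacy_rhs(t + h, y4, params, u_a)
            y = tuple(
                y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
                for i in range(3)
            )
            if min(y) < 0.0:
                y = _clip_negative(y, "legacy model step")
        if not all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at t={day + 1} day; check parameters and step"
            )
        states[day + 1] = y
    return LegacyTrajectory(times=times, states=states)
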