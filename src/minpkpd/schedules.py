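"""Timed dosing schedules for the three therapy channels.

A schedule is a list of (day, amount) events on a 1-based daily grid:
day k covers the continuous-time interval [k-1, k) in days.  Amounts are
mg/mL for the drug channels and Gy for radiotherapy.  Dosing is modeled as
a constant infusion over the administration day — the event amount is the
dose *rate* (amount per day) held for one day — matching the daily
sampling of the simulator; an instantaneous-bolus mode is available via
``mode="bolus"``.

Protocol generators cover the study designs: weekly dosing on days 1, 8,
15, 22, ... and the three radiotherapy protocols (single weekly 5 Gy;
5 Gy x 3 days then 2 Gy x 3 days after two weeks; and the microfraction
variant 5 Gy + 2 x 0.075 Gy then 2 Gy + 2 x 0.075 Gy after two weeks).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ScheduleError, ValidationError

__all__ = [
    "Channel",
    "DoseEvent",
    "DoseSchedule",
    "weekly_schedule",
    "rt_protocol",
    "rate_function",
    "read_schedule_csv",
    "write_schedule_csv",
]


class Channel(enum.Enum):
    """Therapy channel: antiangiogenic drug, immunotherapy or radiotherapy."""

    AG = "AG"
    IM = "IM"
    RT = "RT"

    @property
    def unit(self) -> str:
        return "Gy" if self is Channel.RT else "mg/mL"


@dataclass(frozen=True)
class DoseEvent:
    """One administration: 1-based day and nonnegative amount."""

    day: int
    amount: float

    def __post_init__(self) -> None:
        if self.day < 1 or self.day != int(self.day):
            raise ValidationError("day: must be an integer >= 1")
        if self.amount < 0:
            raise ValidationError("amount: must be >= 0")


@dataclass(frozen=True)
class DoseSchedule:
    """Normalized dosing schedule for one channel.

    Events are merged per day (same-day fractions are summed), sorted, and
    required to fall within the horizon.  ``mode`` selects constant
    infusion over the dosing day (default) or an instantaneous bolus at
    the start of the day.
    """

    channel: Channel
    events: tuple[DoseEvent, ...]
    horizon: int
    mode: str = "infusion"

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValidationError("horizon: must be >= 1")
        if self.mode not in ("infusion", "bolus"):
            raise ValidationError("mode: must be 'infusion' or 'bolus'")
        merged: dict[int, float] = {}
        for event in self.events:
            if event.day > self.horizon:
                raise ValidationError(
                    f"events: day {event.day} exceeds horizon {self.horizon}"
                )
            merged[event.day] = merged.get(event.day, 0.0) + event.amount
        normalized = tuple(
            DoseEvent(day, merged[day]) for day in sorted(merged)
        )
        object.__setattr__(self, "events", normalized)

    @classmethod
    def from_pairs(
        cls,
        channel: Channel,
        pairs: Iterable[tuple[int, float]],
        horizon: int,
        mode: str = "infusion",
    ) -> "DoseSchedule":
        return cls(
            channel=channel,
            events=tuple(DoseEvent(day, amount) for day, amount in pairs),
            horizon=horizon,
            mode=mode,
        )

    @classmethod
    def empty(cls, channel: Channel, horizon: int) -> "DoseSchedule":
        return cls(channel=channel, events=(), horizon=horizon)

    def amount_on(self, day: int) -> float:
        """Total amount administered on a 1-based day (0 if none)."""
        for event in self.events:
            if event.day == day:
                return event.amount
        return 0.0

    def daily_amounts(self, horizon: int | None = None) -> list[float]:
        """Dense per-day amounts over ``horizon`` days (index 0 = day 1)."""
        horizon = self.horizon if horizon is None else horizon
        dense = [0.0] * horizon
        for event in self.events:
            if event.day <= horizon:
                dense[event.day - 1] += event.amount
        return dense

    @property
    def total_amount(self) -> float:
        return sum(event.amount for event in self.events)


def weekly_schedule(channel: Channel, amount: float, horizon: int) -> DoseSchedule:
    """Dose ``amount`` once every week starting on day 1 (days 1, 8, 15, ...)."""
    if amount < 0:
        raise ValidationError("amount: must be >= 0")
    days = range(1, horizon + 1, 7)
    return DoseSchedule.from_pairs(channel, [(d, amount) for d in days], horizon)


def rt_protocol(
    protocol_id: int, horizon: int = 30, microfractions: str = "following-days"
) -> DoseSchedule:
    """Radiotherapy schedule for one of the three study protocols.

    Protocol 1: 5 Gy once weekly (days 1, 8, 15, 22, 29).
    Protocol 2: 5 Gy on days 1-3, then 2 Gy on days 15-17.
    Protocol 3: 5 Gy on day 1 with 0.075 Gy microfractions on days 2-3,
    then 2 Gy on day 15 with 0.075 Gy on days 16-17 — mirroring the 3-day
    span of Protocol 2.  ``microfractions="same-day"`` instead merges the
    microfractions into the main-fraction day.
    """
    if protocol_id == 1:
        pairs = [(d, 5.0) for d in range(1, horizon + 1, 7)]
    elif protocol_id == 2:
        pairs = [(1, 5.0), (2, 5.0), (3, 5.0), (15, 2.0), (16, 2.0), (17, 2.0)]
    elif protocol_id == 3:
        if microfractions == "following-days":
            pairs = [
                (1, 5.0), (2, 0.075), (3, 0.075),
                (15, 2.0), (16, 0.075), (17, 0.075),
            ]
        elif microfractions == "same-day":
            pairs = [(1, 5.15), (15, 2.15)]
        else:
            raise ValidationError(
                "microfractions: must be 'following-days' or 'same-day'"
            )
    else:
        raise ScheduleError(f"unknown radiotherapy protocol id: {protocol_id!r}")
    pairs = [(day, amount) for day, amount in pairs if day <= horizon]
    return DoseSchedule.from_pairs(Channel.RT, pairs, horizon)


def rate_function(schedule: DoseSchedule, t: float) -> float:
    """Piecewise-constant dose rate (amount/day) at continuous time t.

    The event of day k is delivered as a constant rate over [k-1, k);
    t outside [0, horizon] is a domain error.  At t == horizon the rate of
    the final day is returned.
    """
    if not 0.0 <= t <= schedule.horizon:
        raise ScheduleError(
            f"t={t} outside the schedule horizon [0, {schedule.horizon}]"
        )
    day = min(int(math.floor(t)), schedule.horizon - 1) + 1
    return schedule.amount_on(day)


def write_schedule_csv(schedules: Sequence[DoseSchedule], path: str) -> None:
    """Write schedules as CSV with columns channel, day, amount, unit."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "day", "amount", "unit"])
        for schedule in schedules:
            for event in schedule.events:
                writer.writerow(
                    [schedule.channel.value, event.day, repr(event.amount), schedule.channel.unit]
                )


def read_schedule_csv(path: str, horizon: int) -> dict[Channel, DoseSchedule]:
    """Read a channel/day/amount CSV into per-channel schedules."""
    pairs: dict[Channel, list[tuple[int, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"channel", "day", "amount"} <= set(
            reader.fieldnames
        ):
            raise ScheduleError("schedule CSV needs columns channel, day, amount")
        for row in reader:
            try:
                channel = Channel(row["channel"])
            except ValueError as exc:
                raise ScheduleError(f"unknown channel {row['channel']!r}") from exc
            pairs.setdefault(channel, []).append(
                (int(row["day"]), float(row["amount"]))
            )
    return {
        channel: DoseSchedule.from_pairs(channel, events, horizon)
        for channel, events in pairs.items()
    }
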