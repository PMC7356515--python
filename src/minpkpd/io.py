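"""Deterministic writers for trajectories and run summaries."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Mapping

import pandas as pd

from .core import Trajectory
from .experiments import ExperimentSummary
from .parameters import CombinedParameters
from .schedules import Channel, DoseSchedule

__all__ = [
    "TRAJECTORY_COLUMNS",
    "write_trajectory",
    "read_trajectory",
    "schedule_digest",
    "write_summary",
]

TRAJECTORY_COLUMNS = (
    "time_day", "x1_mm3", "x2_mm3", "total_mm3",
    "x3", "xe3", "x4", "xe4", "x5", "xe5",
    "E", "Et_a", "Et_i", "Et_r",
)


def write_trajectory(trajectory: Trajectory | None, path: str) -> None:
    """Write a trajectory CSV with the canonical header, 10 significant digits.

    ``None`` (an empty trajectory) writes a header-only file.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(TRAJECTORY_COLUMNS) + "\n")
        if trajectory is None:
            return
        frame = trajectory.to_frame()[list(TRAJECTORY_COLUMNS)]
        for row in frame.itertuples(index=False):
            fh.write(",".join(f"{value:.10g}" for value in row) + "\n")


def read_trajectory(path: str) -> pd.DataFrame:
    """Read back a trajectory CSV written by :func:`write_trajectory`."""
    return pd.read_csv(path)


def schedule_digest(schedules: Mapping[Channel, DoseSchedule]) -> str:
    """Stable sha256 digest over canonical channel,day,amount lines."""
    lines = []
    for channel in Channel:
        schedule = schedules.get(channel)
        if schedule is None:
            continue
        for event in schedule.events:
            lines.append(f"{channel.value},{event.day},{event.amount!r},{schedule.mode}")
    return hashlib.sha256("\n".join(lines).encode()).hexdigest()


def write_summary(
    summary: ExperimentSummary,
    path: str,
    params: CombinedParameters,
    schedules: Mapping[Channel, DoseSchedule] | None = None,
    horizon: int = 30,
    step: float = 0.01,
) -> None:
    """Write a JSON run summary with a full provenance block.

    The provenance block holds every effective parameter, the schedule
    digest, horizon and step; re-running from it reproduces the outputs
    exactly (the simulator is deterministic).
    """
    payload = {
        "label": summary.label,
        "end_total_volume_mm3": summary.end_total_volume,
        "end_active_volume_mm3": summary.end_active_volume,
        "end_necrotic_volume_mm3": summary.end_necrotic_volume,
        "relative_difference_vs_reference_pct": summary.relative_difference_vs_reference,
        "provenance": {
            "parameters": params.to_dict(),
            "schedule_digest": schedule_digest(schedules or {}),
            "schedules": {
                channel.value: [
                    dataclasses.asdict(event) for event in schedule.events
                ]
                for channel, schedule in (schedules or {}).items()
            },
            "horizon_days": horizon,
            "step_days": step,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
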