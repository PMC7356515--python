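"""Study runners: control, protocol comparison, synergy and resistance sweeps.

Every runner integrates the combined model over a 30-day horizon with
daily sampling and summarizes the day-30 volumes.  "End volume" means the
total tumor volume x1 + x2 (the quantity the stem plots trace); the active
(x1) and necrotic (x2) parts are reported alongside.  The fixed therapy
background for all protocol runs is the antiangiogenic drug at 0.171
mg/mL once weekly and immunotherapy at 0.2 mg/mL once weekly, with the
radiotherapy protocol as the only varied input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core import Trajectory, simulate
from .errors import ValidationError
from .parameters import CombinedParameters, default_combined_parameters
from .schedules import Channel, DoseSchedule, rt_protocol, weekly_schedule

__all__ = [
    "AG_WEEKLY_DOSE",
    "IM_WEEKLY_DOSE",
    "ExperimentSummary",
    "SweepResult",
    "run_control",
    "run_protocol",
    "relative_difference",
    "synergy_sweep",
    "resistance_sweep",
]

AG_WEEKLY_DOSE = 0.171  # mg/mL once weekly
IM_WEEKLY_DOSE = 0.20  # mg/mL once weekly


@dataclass(frozen=True)
class ExperimentSummary:
    """Day-30 (end-of-horizon) volumes of one run, in mm³."""

    label: str
    end_total_volume: float
    end_active_volume: float
    end_necrotic_volume: float
    relative_difference_vs_reference: float | None = None
    trajectory: Trajectory | None = field(default=None, repr=False, compare=False)

    def with_reference(self, reference: "ExperimentSummary") -> "ExperimentSummary":
        """Attach the percent difference of end_total vs a reference run."""
        return ExperimentSummary(
            label=self.label,
            end_total_volume=self.end_total_volume,
            end_active_volume=self.end_active_volume,
            end_necrotic_volume=self.end_necrotic_volume,
            relative_difference_vs_reference=relative_difference(self, reference),
            trajectory=self.trajectory,
        )


@dataclass(frozen=True)
class SweepResult:
    """One-parameter sweep: per-value summaries plus the headline contrast.

    For a synergy sweep ``contrast`` is the fold-reduction of the end
    total volume between the smallest and largest sigma; for a resistance
    sweep it is the percent increase of the end total volume at the
    largest gamma relative to the smallest.
    """

    parameter: str
    table: pd.DataFrame
    contrast: float
    contrast_name: str


def _summarize(label: str, trajectory: Trajectory) -> ExperimentSummary:
    x1, x2 = trajectory.states[-1, 0], trajectory.states[-1, 1]
    return ExperimentSummary(
        label=label,
        end_total_volume=x1 + x2,
        end_active_volume=x1,
        end_necrotic_volume=x2,
        trajectory=trajectory,
    )


def run_control(
    params: CombinedParameters | None = None,
    horizon: int = 30,
    step: float = 0.01,
) -> ExperimentSummary:
    """No-treatment run: pure exponential growth of the active volume."""
    params = params or default_combined_parameters()
    trajectory = simulate(params, None, horizon=horizon, step=step)
    return _summarize("control", trajectory)


def protocol_schedules(
    protocol_id: int,
    horizon: int = 30,
    ag_dose: float = AG_WEEKLY_DOSE,
    im_dose: float = IM_WEEKLY_DOSE,
) -> dict[Channel, DoseSchedule]:
    """Weekly AG + weekly IM plus the requested radiotherapy protocol."""
    return {
        Channel.AG: weekly_schedule(Channel.AG, ag_dose, horizon),
        Channel.IM: weekly_schedule(Channel.IM, im_dose, horizon),
        Channel.RT: rt_protocol(protocol_id, horizon),
    }


def run_protocol(
    protocol_id: int,
    params: CombinedParameters | None = None,
    horizon: int = 30,
    step: float = 0.01,
    ag_dose: float = AG_WEEKLY_DOSE,
    im_dose: float = IM_WEEKLY_DOSE,
) -> ExperimentSummary:
    """Full combination run with RT per protocol and fixed AG/IM weekly."""
    params = params or default_combined_parameters()
    schedules = protocol_schedules(protocol_id, horizon, ag_dose, im_dose)
    trajectory = simulate(params, schedules, horizon=horizon, step=step)
    return _summarize(f"protocol-{protocol_id}", trajectory)


def relative_difference(
    summary_b: ExperimentSummary, summary_a: ExperimentSummary
) -> float:
    """Percent difference 100*(B - A)/A of end total volumes."""
    if summary_a.end_total_volume <= 0:
        raise ValidationError("end_total_volume: reference volume must be > 0")
    return (
        100.0
        * (summary_b.end_total_volume - summary_a.end_total_volume)
        / summary_a.end_total_volume
    )


def _sweep(
    parameter: str,
    values: Sequence[float],
    params: CombinedParameters,
    protocol_id: int,
    horizon: int,
    step: float,
) -> pd.DataFrame:
    rows = []
    for value in values:
        run = run_protocol(
            protocol_id, params.replace(**{parameter: float(value)}), horizon, step
        )
        rows.append(
            {
                parameter: float(value),
                "label": f"protocol-{protocol_id} {parameter}={value:g}",
                "end_total_mm3": run.end_total_volume,
                "end_active_mm3": run.end_active_volume,
                "end_necrotic_mm3": run.end_necrotic_volume,
            }
        )
    return pd.DataFrame(rows)


def synergy_sweep(
    params: CombinedParameters | None = None,
    protocol_id: int = 3,
    sigma_values: Sequence[float] = (1.0, 8.0),
    horizon: int = 30,
    step: float = 0.01,
) -> SweepResult:
    """Vary the synergy coefficient sigma with everything else fixed.

    The contrast is the fold-reduction of the end total volume between the
    extreme sigma values (volume at min sigma over volume at max sigma).
    """
    if not sigma_values:
        raise ValidationError("sigma_values: must be nonempty")
    if any(v < 0 for v in sigma_values):
        raise ValidationError("sigma_values: must be >= 0")
    params = params or default_combined_parameters()
    table = _sweep("sigma", sigma_values, params, protocol_id, horizon, step)
    lo = table.loc[table["sigma"].idxmin(), "end_total_mm3"]
    hi = table.loc[table["sigma"].idxmax(), "end_total_mm3"]
    return SweepResult(
        parameter="sigma",
        table=table,
        contrast=float(lo / hi),
        contrast_name="fold_reduction_end_total",
    )


def resistance_sweep(
    params: CombinedParameters | None = None,
    protocol_id: int = 3,
    gamma_values: Sequence[float] = (1.0, 8.0),
    horizon: int = 30,
    step: float = 0.01,
) -> SweepResult:
    """Vary the response exponent gamma at nominal synergy sigma = 4.

    The contrast is the percent increase of the end total volume at the
    largest gamma (most resistant) relative to the smallest (most
    responsive).
    """
    if not gamma_values:
        raise ValidationError("gamma_values: must be nonempty")
    if any(v <= 0 for v in gamma_values):
        raise ValidationError("gamma_values: must be > 0")
    params = (params or default_combined_parameters()).replace(sigma=4.0)
    table = _sweep("gamma", gamma_values, params, protocol_id, horizon, step)
    lo = table.loc[table["gamma"].idxmin(), "end_total_mm3"]
    hi = table.loc[table["gamma"].idxmax(), "end_total_mm3"]
    return SweepResult(
        parameter="gamma",
        table=table,
        contrast=float(100.0 * (hi - lo) / lo),
        contrast_name="percent_increase_end_total",
    )
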