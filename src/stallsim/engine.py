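"""Monthly time-step simulator and trace output.

Each step (30.4 days by default) proceeds in a fixed order:

1. potential daily gain from the Gompertz growth curve,
2. potential milk yield from the lactation curve, times the configurable
   age and body-condition modifiers,
3. factorial potential ME and uCP requirements,
4. voluntary DMI and ME intake (condition-scaled, offer-capped),
5. ME partitioning, mobilization and actual performance,
6. state update: BW by the day's actual gain times days-in-step, age by
   days/365.25, lactation month by one while lactating.

The run is fully deterministic: identical scenarios yield identical traces.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

from .core import AnimalState, Scenario
from .intake import IntakeResult, voluntary_dmi
from .partition import PartitionResult, partition_step
from .physiology import (
    condition_index,
    growth_envelope,
    potential_growth_rate,
    potential_milk_yield,
)
from .requirements import RequirementBreakdown, default_gain_table, total_requirements

__all__ = ["StepRecord", "SimulationTrace", "SimulationError", "run_simulation",
           "write_trace", "read_trace"]


class SimulationError(RuntimeError):
    """A state invariant was violated during a run."""


@dataclass(frozen=True)
class StepRecord:
    """Everything computed during one monthly step."""

    step: int  # 1-based
    days_in_step: float
    state: AnimalState  # state at the start of the step
    condition: float  # body-weight condition index
    potential_gain: float  # kg/day
    potential_milk: float  # kg/day, after modifiers
    intake: IntakeResult
    requirements: RequirementBreakdown
    partition: PartitionResult


@dataclass
class SimulationTrace:
    """Per-step records of one simulation plus summary accessors."""

    scenario: Scenario
    records: list[StepRecord] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.records)

    @property
    def final_body_weight(self) -> float:
        last = self.records[-1]
        return last.state.body_weight + last.partition.actual_gain * last.days_in_step

    @property
    def mean_dmi(self) -> float:
        return sum(r.intake.scaled_dmi for r in self.records) / self.n_steps

    @property
    def mean_milk(self) -> float:
        return sum(r.partition.actual_milk for r in self.records) / self.n_steps

    @property
    def cumulative_milk(self) -> float:
        return sum(r.partition.actual_milk * r.days_in_step for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        cum_milk = 0.0
        cum_dmi = 0.0
        for r in self.records:
            cum_milk += r.partition.actual_milk * r.days_in_step
            cum_dmi += r.intake.scaled_dmi
            rows.append(
                {
                    "step": r.step,
                    "days_in_step": r.days_in_step,
                    "age_years": r.state.age,
                    "body_weight_kg": r.state.body_weight,
                    "lactation_month": r.state.lactation_month,
                    "gestation_day": r.state.gestation_day,
                    "condition_index": r.condition,
                    "potential_gain_kg_d": r.potential_gain,
                    "potential_milk_kg_d": r.potential_milk,
                    "ndf_capacity_kg_d": r.intake.ndf_capacity,
                    "physical_dmi_kg_d": r.intake.physical_dmi,
                    "physiological_dmi_kg_d": r.intake.physiological_dmi,
                    "raw_dmi_kg_d": r.intake.raw_dmi,
                    "dmi_kg_d": r.intake.scaled_dmi,
                    "mei_mj_d": r.intake.mei,
                    "me_req_total_mj_d": r.requirements.me_total,
                    "ucp_req_total_g_d": r.requirements.ucp_total,
                    "me_to_milk_mj_d": r.partition.me_to_milk,
                    "me_to_gain_mj_d": r.partition.me_to_gain,
                    "mobilized_bw_kg_d": r.partition.mobilized_bw,
                    "actual_milk_kg_d": r.partition.actual_milk,
                    "actual_gain_kg_d": r.partition.actual_gain,
                    "lactation_stage": r.partition.lactation_stage,
                    "cumulative_milk_kg": cum_milk,
                    "mean_dmi_to_date_kg_d": cum_dmi / r.step,
                }
            )
        return pd.DataFrame(rows)


def run_simulation(
    scenario: Scenario,
    *,
    milk_age_factor: float = 1.0,
    condition_scales_milk: bool = False,
) -> SimulationTrace:
    """Run a scenario for its configured number of monthly steps.

    ``milk_age_factor`` and ``condition_scales_milk`` are the hooks through
    which the potential milk yield can be modified by cow age and body
    condition before requirements and partitioning; by default the age
    factor is 1 and body condition acts on intake only.
    """
    breed = scenario.breed
    envelope = growth_envelope(breed)
    table = default_gain_table()
    state = copy.deepcopy(scenario.initial_state)
    trace = SimulationTrace(scenario=scenario)
    days = scenario.days_per_step

    for step in range(1, scenario.n_steps + 1):
        if state.body_weight <= 0 or not math.isfinite(state.body_weight):
            raise SimulationError(f"non-positive body weight entering step {step}")

        ci = condition_index(state.body_weight, state.age, envelope)
        pot_gain = potential_growth_rate(
            max(state.body_weight, breed.birth_weight), breed
        )
        pot_milk = potential_milk_yield(state.lactation_month, breed)
        pot_milk *= milk_age_factor * (ci if condition_scales_milk else 1.0)

        req = total_requirements(state, breed, scenario, pot_gain, pot_milk, table)
        ir = voluntary_dmi(state.body_weight, req.me_total, scenario.ration, ci)
        pr = partition_step(
            ir.mei, req, state, breed, scenario.ration, pot_milk, table
        )

        trace.records.append(
            StepRecord(
                step=step,
                days_in_step=days,
                state=copy.deepcopy(state),
                condition=ci,
                potential_gain=pot_gain,
                potential_milk=pot_milk,
                intake=ir,
                requirements=req,
                partition=pr,
            )
        )

        # state update
        state.body_weight += pr.actual_gain * days
        state.age += days / 365.25
        if state.lactation_month > 0:
            state.lactation_month += 1
            if state.lactation_month > breed.lactation_length:
                state.lactation_month = 0
        if state.gestation_day > 0:
            state.gestation_day = min(state.gestation_day + days, 283.0)

        if state.body_weight <= 0:
            raise SimulationError(
                f"body weight fell to {state.body_weight:.1f} kg after step {step}"
            )

    return trace


_SUMMARY_STEP = "summary"


def write_trace(trace: SimulationTrace, path: Union[str, Path]) -> None:
    """Write one CSV row per step plus a final summary row.

    The summary row carries the run's headline numbers: mean daily DMI,
    final body weight and mean daily milk yield.
    """
    if trace.n_steps == 0:
        raise ValueError("cannot write an empty trace")
    df = trace.to_dataframe()
    summary = {c: "" for c in df.columns}
    summary.update(
        step=_SUMMARY_STEP,
        dmi_kg_d=trace.mean_dmi,
        body_weight_kg=trace.final_body_weight,
        actual_milk_kg_d=trace.mean_milk,
        cumulative_milk_kg=trace.cumulative_milk,
    )
    out = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    out.to_csv(path, index=False)


def read_trace(path: Union[str, Path]) -> pd.DataFrame:
    """Read the per-step rows of a trace CSV (the summary row is dropped)."""
    df = pd.read_csv(path, dtype={"step": str})
    df = df[df["step"] != _SUMMARY_STEP].copy()
    df["step"] = df["step"].astype(int)
    return df.reset_index(drop=True)
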