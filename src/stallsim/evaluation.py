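"""Model-adequacy statistics and the observed-vs-predicted harness.

For a set of paired observed/predicted treatment means the module computes

* MBE, the mean bias error, sum(observed - predicted)/q — negative values
  mean the model over-predicts;
* RMSEP, the root mean squared error of prediction,
  sqrt(sum((observed - predicted)^2)/q);
* RPE, the relative prediction error: RMSEP as a percentage of the mean
  observed value;

and classifies accuracy from the RPE: excellent below 10%, good at 10-20%,
fair at 21-30% (the closed printed interval ends included), poor above 30%.

A small seeded scenario generator produces randomized but valid simulation
inputs for property and fuzz tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core import AnimalState, BreedParameters, Ration, Scenario
from .engine import SimulationTrace

__all__ = [
    "PairedSeries",
    "EvaluationReport",
    "mean_bias_error",
    "rmsep",
    "rpe",
    "accuracy_class",
    "evaluate_series",
    "evaluate_against_observed",
    "load_observed",
    "bundled_observed",
    "reports_to_dataframe",
    "synthetic_scenarios",
]

#: trace summary statistic used for each evaluation parameter
PARAMETERS = ("voluntary_dmi", "final_body_weight", "milk_yield")


@dataclass(frozen=True)
class PairedSeries:
    """Matched observed and predicted values for one parameter."""

    name: str
    units: str
    observed: tuple
    predicted: tuple

    def __post_init__(self):
        obs = tuple(float(v) for v in self.observed)
        pred = tuple(float(v) for v in self.predicted)
        if len(obs) != len(pred) or len(obs) < 1:
            raise ValueError(
                f"observed/predicted must have equal length >= 1, "
                f"got {len(obs)} and {len(pred)}"
            )
        if not all(math.isfinite(v) for v in obs + pred):
            raise ValueError("all values must be finite")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "predicted", pred)


@dataclass(frozen=True)
class EvaluationReport:
    """Adequacy statistics for one predicted parameter."""

    parameter: str
    units: str
    mbe: float
    rmsep: float
    rpe: float  # % of the mean observed value
    accuracy_class: str


def mean_bias_error(series: PairedSeries) -> float:
    """Mean of observed - predicted; negative means over-prediction."""
    obs = np.asarray(series.observed)
    pred = np.asarray(series.predicted)
    return float(np.mean(obs - pred))


def rmsep(series: PairedSeries) -> float:
    """Root mean squared error of prediction."""
    obs = np.asarray(series.observed)
    pred = np.asarray(series.predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def rpe(series: PairedSeries) -> float:
    """RMSEP as a percentage of the mean observed value."""
    mean_obs = float(np.mean(series.observed))
    if mean_obs == 0:
        raise ValueError("mean observed value is zero; RPE undefined")
    return 100.0 * rmsep(series) / mean_obs


def accuracy_class(rpe_value: float) -> str:
    """Classify prediction accuracy from the relative prediction error."""
    if rpe_value < 0:
        raise ValueError(f"RPE must be >= 0, got {rpe_value}")
    if rpe_value < 10:
        return "excellent"
    if rpe_value <= 20:
        return "good"
    if rpe_value <= 30:
        return "fair"
    return "poor"


def evaluate_series(series: PairedSeries) -> EvaluationReport:
    """Compute all adequacy statistics for one paired series."""
    r = rmsep(series)
    p = rpe(series)
    return EvaluationReport(
        parameter=series.name,
        units=series.units,
        mbe=mean_bias_error(series),
        rmsep=r,
        rpe=p,
        accuracy_class=accuracy_class(p),
    )


_UNITS = {
    "voluntary_dmi": "kg/animal/day",
    "final_body_weight": "kg/animal",
    "milk_yield": "kg/animal/day",
}


def _trace_statistic(trace: SimulationTrace, parameter: str) -> float:
    if parameter == "voluntary_dmi":
        return trace.mean_dmi
    if parameter == "final_body_weight":
        return trace.final_body_weight
    if parameter == "milk_yield":
        return trace.mean_milk
    raise KeyError(
        f"unknown parameter {parameter!r}; expected one of {PARAMETERS}"
    )


def evaluate_against_observed(
    traces: Mapping[str, SimulationTrace],
    observed: pd.DataFrame,
) -> dict[str, EvaluationReport]:
    """Compare simulation traces against observed treatment means.

    ``traces`` maps treatment name to trace; ``observed`` needs columns
    ``parameter``, ``treatment`` and ``value`` with one row per pair.
    Treatments present in ``observed`` but missing from ``traces`` (or vice
    versa) raise a naming error.
    """
    required = {"parameter", "treatment", "value"}
    if not required.issubset(observed.columns):
        raise KeyError(f"observed table must have columns {sorted(required)}")
    reports = {}
    for parameter, grp in observed.groupby("parameter", sort=False):
        if parameter not in PARAMETERS:
            raise KeyError(
                f"unknown parameter {parameter!r}; expected one of {PARAMETERS}"
            )
        obs, pred = [], []
        for _, row in grp.iterrows():
            treatment = row["treatment"]
            if treatment not in traces:
                raise KeyError(
                    f"no trace supplied for treatment {treatment!r} "
                    f"(parameter {parameter!r})"
                )
            obs.append(float(row["value"]))
            pred.append(_trace_statistic(traces[treatment], parameter))
        series = PairedSeries(
            name=parameter, units=_UNITS[parameter],
            observed=tuple(obs), predicted=tuple(pred),
        )
        reports[parameter] = evaluate_series(series)
    return reports


def reports_to_dataframe(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Flatten evaluation reports to a table (one row per parameter)."""
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "units": r.units,
                "mbe": r.mbe,
                "rmsep": r.rmsep,
                "rpe_percent": r.rpe,
                "accuracy_class": r.accuracy_class,
            }
            for r in reports.values()
        ]
    )


def load_observed(path: Union[str, Path]) -> pd.DataFrame:
    """Load an observed-values CSV (columns parameter, treatment, value)."""
    return pd.read_csv(path)


def bundled_observed() -> pd.DataFrame:
    """Observed treatment means (and the reference herd model's published
    predictions, as plain input data) from the bundled Ethiopian stall-fed
    dairy trial."""
    ref = resources.files("stallsim.data").joinpath("ethiopia_stallfed_observed.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def synthetic_scenarios(seed: int, n: int) -> list[Scenario]:
    """Generate ``n`` randomized valid scenarios for property testing.

    Draws span realistic (sub-)tropical dairy ranges: body weight 150-550
    kg, diet ME 6-12 MJ/kg DM, NDF 0.35-0.75 kg/kg DM, peak milk 5-25
    kg/day, lactation length 8-12 months.  Identical seeds give identical
    lists.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    scenarios = []
    for i in range(n):
        species = rng.choice(["crossbred", "indicus"])
        lact_len = int(rng.integers(8, 13))
        peak_month = int(rng.integers(1, 4))
        max_att = float(rng.uniform(480, 700))
        min_mat = float(rng.uniform(150, 0.6 * max_att))
        bw = float(rng.uniform(150, 550))
        lact_month = int(rng.integers(0, lact_len + 1))
        breed = BreedParameters(
            name=f"synthetic-{i}",
            species_class=str(species),
            sex="female",
            birth_weight=float(rng.uniform(18, 35)),
            max_attainable_weight=max_att,
            min_mature_weight=min_mat,
            peak_milk_yield=float(rng.uniform(5, 25)),
            peak_month=peak_month,
            lactation_length=lact_len,
            milk_fat=float(rng.uniform(35, 55)),
            milk_protein=float(rng.uniform(25, 38)),
        )
        state = AnimalState(
            age=float(rng.uniform(2.0, 10.0)),
            body_weight=bw,
            lactation_month=lact_month,
            gestation_day=0.0,
            parity=int(rng.integers(0, 6)),
        )
        ration = Ration(
            dm=float(rng.uniform(850, 920)),
            me=float(rng.uniform(6.0, 12.0)),
            ndf=float(rng.uniform(0.35, 0.75)),
            cp=float(rng.uniform(60, 180)),
            contains_concentrate=bool(rng.integers(0, 2)),
            offered_dm=math.inf,
        )
        scenarios.append(
            Scenario(
                breed=breed,
                initial_state=state,
                ration=ration,
                n_steps=int(rng.integers(1, 13)),
                horizontal_distance=float(rng.uniform(0, 2000)),
                vertical_distance=float(rng.uniform(0, 100)),
            )
        )
    return scenarios
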