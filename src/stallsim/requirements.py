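"""Factorial metabolizable-energy and utilizable-crude-protein requirements.

Requirements are computed per metabolic function and summed:

    ME_total  = ME_m + ME_l + ME_a + ME_g + ME_pf          (MJ/day)
    uCP_total = uCP_m + uCP_l + uCP_g + uCP_pf             (g/day)

where the subscripts denote maintenance, lactation, activity, gestation and
protein/fat deposition (growth).  Maintenance scales with metabolic body
weight (BW^0.75) using coefficients calibrated for (sub-)tropical cattle
(0.631 MJ/kg^0.75/day for adults, 0.53 for calves).  Milk energy depends on
the fat concentration; activity energy on the distances walked; gestation
energy is counted only over the last eight weeks before term.

The energy and net-protein cost of one kg of body-weight change is
age-dependent (cattle in the (Sub-)Tropics often show retarded weight for
age) and tabulated at age knots per sex and breed class; between knots the
cost is interpolated linearly, beyond the last knot it is constant.  ME for
gain divides the net-energy cost by the deposition efficiency k_pf = 0.4.

The uCP (utilizable crude protein: undegraded feed protein plus microbial
protein at the duodenum) requirements for maintenance, lactation and
gestation use simple coefficient forms in the style of the German feed
evaluation system; the coefficients are package defaults, exposed as
arguments, and the protein balance does not feed back on simulated
performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .core import AnimalState, BreedParameters, Scenario

__all__ = [
    "GainCostTable",
    "default_gain_table",
    "RequirementBreakdown",
    "me_maintenance",
    "me_per_kg_milk",
    "me_lactation",
    "me_activity",
    "me_gestation",
    "me_per_kg_gain",
    "ucp_gain",
    "ucp_maintenance",
    "ucp_lactation",
    "ucp_gestation",
    "total_requirements",
]

# maintenance ME per kg metabolic weight, MJ/kg^0.75/day
B_ADULT = 0.631
B_CALF = 0.53
CALF_AGE_LIMIT = 1.0  # years; younger animals use the calf coefficient

KPF = 0.4  # efficiency of ME use for protein and fat deposition
KA = 0.7  # efficiency of ME use for activity
KG = 0.2  # efficiency of ME use for gestation
UCP_GAIN_FACTOR = 2.1  # uCP needed per g of net protein accreted

GESTATION_TERM = 280.0  # days, configurable default
GESTATION_WINDOW = 56.0  # days before term over which ME_g is counted

# stand-in coefficients for the non-growth uCP components (g/day terms)
UCP_M_COEFF = 3.9  # g/kg^0.75/day
UCP_L_COEFF = 85.0  # g/kg milk
UCP_G_CONST = 135.0  # g/day during the last eight weeks of gestation


@dataclass(frozen=True)
class GainCostTable:
    """Age-knot tables of the net energy and net protein cost of BW change.

    ``energy`` maps (sex, species_class) to (age knots, NE MJ/kg BW change);
    ``protein`` likewise to net protein g/kg BW gain.
    """

    energy: dict
    protein: dict
    kpf: float = KPF

    def ne_per_kg(self, age: float, sex: str, species_class: str) -> float:
        """Net energy cost of one kg BW change (MJ/kg) at the given age."""
        knots, values = self._lookup(self.energy, sex, species_class)
        return float(np.interp(age, knots, values))

    def np_per_kg(self, age: float, sex: str, species_class: str) -> float:
        """Net protein content of one kg BW gain (g/kg) at the given age."""
        knots, values = self._lookup(self.protein, sex, species_class)
        return float(np.interp(age, knots, values))

    @staticmethod
    def _lookup(table: dict, sex: str, species_class: str):
        try:
            return table[(sex, species_class)]
        except KeyError:
            raise LookupError(
                f"no gain-cost entry for sex={sex!r}, species_class={species_class!r}"
            ) from None


def _load_table(filename: str, value_col: str) -> dict:
    ref = resources.files("stallsim.data").joinpath(filename)
    with ref.open() as fh:
        df = pd.read_csv(fh)
    out = {}
    for (sex, cls), grp in df.groupby(["sex", "species_class"]):
        grp = grp.sort_values("age_years")
        out[(sex, cls)] = (
            grp["age_years"].to_numpy(float),
            grp[value_col].to_numpy(float),
        )
    return out


@lru_cache(maxsize=1)
def default_gain_table() -> GainCostTable:
    """The packaged (sub-)tropical gain-cost tables."""
    return GainCostTable(
        energy=_load_table("gain_energy.csv", "ne_mj_per_kg"),
        protein=_load_table("gain_protein.csv", "np_g_per_kg"),
    )


@dataclass(frozen=True)
class RequirementBreakdown:
    """Per-function ME (MJ/day) and uCP (g/day) requirements."""

    me_maintenance: float
    me_lactation: float
    me_activity: float
    me_gestation: float
    me_gain: float
    ucp_maintenance: float
    ucp_lactation: float
    ucp_gestation: float
    ucp_gain: float

    @property
    def me_total(self) -> float:
        return (
            self.me_maintenance
            + self.me_lactation
            + self.me_activity
            + self.me_gestation
            + self.me_gain
        )

    @property
    def ucp_total(self) -> float:
        return (
            self.ucp_maintenance
            + self.ucp_lactation
            + self.ucp_gestation
            + self.ucp_gain
        )


def me_maintenance(bw: float, is_calf: bool = False) -> float:
    """Maintenance ME (MJ/day): b * BW^0.75."""
    if bw <= 0:
        raise ValueError(f"body weight must be > 0, got {bw}")
    b = B_CALF if is_calf else B_ADULT
    return b * bw**0.75


def me_per_kg_milk(milk_fat: float, kl: float) -> float:
    """ME requirement per kg of milk (MJ/kg): (0.041*fat + 1.51) / kl."""
    if kl <= 0:
        raise ValueError(f"kl must be > 0, got {kl}")
    return (0.041 * milk_fat + 1.51) / kl


def me_lactation(potential_yield: float, milk_fat: float, kl: float) -> float:
    """Lactation ME (MJ/day) for the given potential milk yield."""
    if potential_yield < 0:
        raise ValueError(f"potential_yield must be >= 0, got {potential_yield}")
    return me_per_kg_milk(milk_fat, kl) * potential_yield


def me_activity(bw: float, horiz: float, vert: float) -> float:
    """Activity ME (MJ/day) for daily horizontal/vertical distances in m."""
    if horiz < 0 or vert < 0:
        raise ValueError("distances must be >= 0")
    net = (2.6 * bw * horiz) / 1e6 + (28.0 * bw * vert) / 1e6
    return net / KA


def me_gestation(gestation_day: float, term: float = GESTATION_TERM) -> float:
    """Gestation ME (MJ/day), non-zero only in the last eight weeks."""
    if gestation_day < 0:
        raise ValueError(f"gestation_day must be >= 0, got {gestation_day}")
    if gestation_day == 0 or gestation_day < term - GESTATION_WINDOW:
        return 0.0
    return 0.044 * math.exp(0.0165 * gestation_day) / KG


def me_per_kg_gain(
    age: float, sex: str, species_class: str, table: GainCostTable | None = None
) -> float:
    """ME cost of one kg BW gain (MJ/kg): age-interpolated NE / k_pf."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    table = table or default_gain_table()
    return table.ne_per_kg(age, sex, species_class) / table.kpf


def ucp_gain(
    age: float,
    sex: str,
    species_class: str,
    gain: float,
    table: GainCostTable | None = None,
) -> float:
    """uCP (g/day) for BW gain: protein content * gain * 2.1."""
    if gain < 0:
        raise ValueError(f"gain must be >= 0, got {gain}")
    table = table or default_gain_table()
    return table.np_per_kg(age, sex, species_class) * gain * UCP_GAIN_FACTOR


def ucp_maintenance(bw: float, coeff: float = UCP_M_COEFF) -> float:
    """Maintenance uCP (g/day), scaling with metabolic body weight."""
    return coeff * bw**0.75


def ucp_lactation(milk_yield: float, coeff: float = UCP_L_COEFF) -> float:
    """Lactation uCP (g/day), proportional to milk yield."""
    return coeff * max(milk_yield, 0.0)


def ucp_gestation(
    gestation_day: float, term: float = GESTATION_TERM, const: float = UCP_G_CONST
) -> float:
    """Gestation uCP (g/day) during the last eight weeks before term."""
    if gestation_day == 0 or gestation_day < term - GESTATION_WINDOW:
        return 0.0
    return const


def total_requirements(
    state: AnimalState,
    breed: BreedParameters,
    scenario: Scenario,
    potential_gain: float,
    potential_yield: float,
    table: GainCostTable | None = None,
) -> RequirementBreakdown:
    """Assemble the full factorial requirement breakdown for one animal-day.

    ``potential_gain`` below zero contributes no growth requirement (body
    losses are the partitioning step's business, not a requirement).
    """
    table = table or default_gain_table()
    is_calf = state.age < CALF_AGE_LIMIT
    gain = max(potential_gain, 0.0)
    return RequirementBreakdown(
        me_maintenance=me_maintenance(state.body_weight, is_calf),
        me_lactation=me_lactation(potential_yield, breed.milk_fat, breed.kl),
        me_activity=me_activity(
            state.body_weight, scenario.horizontal_distance, scenario.vertical_distance
        ),
        me_gestation=me_gestation(state.gestation_day),
        me_gain=me_per_kg_gain(state.age, breed.sex, breed.species_class, table) * gain,
        ucp_maintenance=ucp_maintenance(state.body_weight),
        ucp_lactation=ucp_lactation(potential_yield),
        ucp_gestation=ucp_gestation(state.gestation_day),
        ucp_gain=ucp_gain(state.age, breed.sex, breed.species_class, gain, table),
    )
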