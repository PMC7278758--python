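"""Allocation of one day's ME intake among body functions.

The partitioning rules decide how much of the metabolizable energy intake
(MEI) goes to maintenance, activity, gestation, milk and body-weight gain,
and when body reserves are mobilized:

* Maintenance, activity and gestation are obligations served first.
* Of the surplus ("MEI available for performance"), a lactation-stage
  fraction goes to milk and the remainder to gain.  With concentrate in the
  diet the milk fractions are 100/88/80% in early/mid/late lactation; on
  forage-only diets 100/85/74%.
* Early lactation (months 1-3): if milk funded from MEI falls short of 60%
  of the potential yield, body reserves are mobilized to close the gap, at
  most 0.23% of body weight per day.  If MEI does not even cover the
  obligations, reserves are mobilized for survival first, against the same
  daily cap.
* Mid and late lactation: no mobilization for milk; if MEI stays below
  maintenance, milk production ceases.

Mobilized tissue releases its age-specific net-energy content (the same
table that prices deposition) and is credited to the destination function
with an efficiency of 0.84.  All flows are expressed in ME terms so that
the ledger closes exactly:  MEI + mobilized ME = sum of allocations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AnimalState, BreedParameters, Ration
from .requirements import (
    GainCostTable,
    RequirementBreakdown,
    default_gain_table,
    me_per_kg_gain,
    me_per_kg_milk,
)

__all__ = [
    "LactationStage",
    "StageFractions",
    "STAGE_FRACTIONS",
    "lactation_stage",
    "PartitionResult",
    "partition_step",
    "MOBILIZATION_CAP_FRACTION",
    "MOBILIZATION_EFFICIENCY",
    "MOBILIZATION_MILK_SHARE",
]

LactationStage = str  # "early" | "mid" | "late" | "dry"

MOBILIZATION_CAP_FRACTION = 0.0023  # kg mobilizable per kg BW per day
MOBILIZATION_EFFICIENCY = 0.84  # NE from reserves -> NE at destination
MOBILIZATION_MILK_SHARE = 0.60  # mobilization tops milk up to this x potential
EARLY_MONTHS = 3  # months of lactation counted as "early"
LATE_MONTHS = 3  # final months of lactation counted as "late"


@dataclass(frozen=True)
class StageFractions:
    """Share of performance MEI routed to milk, by lactation stage."""

    early: float = 1.0
    mid: float = 0.85
    late: float = 0.74

    def for_stage(self, stage: LactationStage) -> float:
        if stage == "dry":
            return 0.0
        return getattr(self, stage)


STAGE_FRACTIONS = {
    True: StageFractions(early=1.0, mid=0.88, late=0.80),  # concentrate diets
    False: StageFractions(early=1.0, mid=0.85, late=0.74),  # forage-only diets
}


def lactation_stage(n: float, lactation_length: float) -> LactationStage:
    """Classify month ``n`` of lactation (0 = dry)."""
    if n < 0 or n > lactation_length:
        raise ValueError(f"lactation month {n} outside [0, {lactation_length}]")
    if n == 0:
        return "dry"
    if n <= EARLY_MONTHS:
        return "early"
    if n > lactation_length - LATE_MONTHS:
        return "late"
    return "mid"


@dataclass(frozen=True)
class PartitionResult:
    """Where one day's MEI (plus any mobilized reserves) ended up."""

    mei: float  # MJ/day
    me_to_maintenance: float
    me_to_activity: float
    me_to_gestation: float
    me_to_milk: float
    me_to_gain: float
    mobilized_bw: float  # kg/day, >= 0
    mobilized_me: float  # MJ/day credited from reserves
    actual_milk: float  # kg/day
    actual_gain: float  # kg/day, negative when mobilizing
    lactation_stage: LactationStage


def partition_step(
    mei: float,
    req: RequirementBreakdown,
    state: AnimalState,
    breed: BreedParameters,
    ration: Ration,
    potential_milk: float,
    table: GainCostTable | None = None,
) -> PartitionResult:
    """Allocate one day's MEI and decide mobilization.

    ``potential_milk`` is the (condition-modified) potential yield for the
    current lactation month; actual milk never exceeds it.
    """
    if mei < 0:
        raise ValueError(f"mei must be >= 0, got {mei}")
    table = table or default_gain_table()

    stage = lactation_stage(state.lactation_month, breed.lactation_length)
    fractions = STAGE_FRACTIONS[ration.contains_concentrate]
    milk_fraction = fractions.for_stage(stage)

    ne_per_kg_bw = table.ne_per_kg(state.age, breed.sex, breed.species_class)
    gain_cost = me_per_kg_gain(state.age, breed.sex, breed.species_class, table)
    milk_cost_me = me_per_kg_milk(breed.milk_fat, breed.kl)  # MJ ME/kg milk
    milk_cost_ne = milk_cost_me * breed.kl  # MJ NE/kg milk
    mob_cap = MOBILIZATION_CAP_FRACTION * state.body_weight  # kg/day
    # milk obtainable per kg of mobilized body weight
    milk_per_kg_mob = ne_per_kg_bw * MOBILIZATION_EFFICIENCY / milk_cost_ne

    obligations = req.me_maintenance + req.me_activity + req.me_gestation
    mobilized = 0.0
    mobilized_me = 0.0

    if mei >= obligations:
        me_maint = req.me_maintenance
        me_act = req.me_activity
        me_gest = req.me_gestation
        surplus = mei - obligations

        me_to_milk = min(milk_fraction * surplus, potential_milk * milk_cost_me)
        me_to_gain = surplus - me_to_milk
        milk = me_to_milk / milk_cost_me if milk_cost_me > 0 else 0.0

        if stage == "early" and milk < MOBILIZATION_MILK_SHARE * potential_milk:
            target = MOBILIZATION_MILK_SHARE * potential_milk
            need_kg = (target - milk) / milk_per_kg_mob
            mobilized = min(need_kg, mob_cap)
            extra_milk = mobilized * milk_per_kg_mob
            milk += extra_milk
            mobilized_me = extra_milk * milk_cost_me
            me_to_milk += mobilized_me
    else:
        # survival: reserves cover the obligation deficit first
        deficit = obligations - mei
        survival_kg = deficit / (ne_per_kg_bw * MOBILIZATION_EFFICIENCY)
        mobilized = min(survival_kg, mob_cap)
        survival_credit = mobilized * ne_per_kg_bw * MOBILIZATION_EFFICIENCY
        covered = mei + survival_credit
        me_maint = min(req.me_maintenance, covered)
        covered -= me_maint
        me_act = min(req.me_activity, covered)
        covered -= me_act
        me_gest = min(req.me_gestation, covered)
        mobilized_me = survival_credit
        me_to_gain = 0.0
        milk = 0.0
        me_to_milk = 0.0

        if stage == "early":
            # any mobilization headroom left funds milk, up to 60% of potential
            headroom = mob_cap - mobilized
            target = MOBILIZATION_MILK_SHARE * potential_milk
            need_kg = target / milk_per_kg_mob
            milk_kg_mob = min(need_kg, headroom)
            milk = milk_kg_mob * milk_per_kg_mob
            me_to_milk = milk * milk_cost_me
            mobilized += milk_kg_mob
            mobilized_me += me_to_milk

    actual_gain = me_to_gain / gain_cost - mobilized

    return PartitionResult(
        mei=mei,
        me_to_maintenance=me_maint,
        me_to_activity=me_act,
        me_to_gestation=me_gest,
        me_to_milk=me_to_milk,
        me_to_gain=me_to_gain,
        mobilized_bw=mobilized,
        mobilized_me=mobilized_me,
        actual_milk=milk,
        actual_gain=actual_gain,
        lactation_stage=stage,
    )
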