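"""Domain types and scenario configuration I/O.

A simulation scenario bundles four things: the breed (genetic constants),
one animal's initial state, the ration on offer, and the run settings
(number of monthly steps, daily activity distances).  Scenarios are stored
as flat YAML files, one scenario per file; two evaluation scenarios from a
stall-fed dairy trial in Ethiopia (a maize-lablab stover diet and an
oats-vetch hay diet) ship with the package.

All units follow the conventions used throughout the package:
weights in kg, energy in MJ, protein in g, yields in kg/animal/day,
diet concentrations per kg of dry matter (DM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "SpeciesClass",
    "Sex",
    "BreedParameters",
    "AnimalState",
    "Ration",
    "Scenario",
    "SchemaError",
    "ValidationError",
    "read_scenario",
    "write_scenario",
    "builtin_fixture",
    "FIXTURE_NAMES",
]

# canonical efficiency of ME use for lactation by breed class
KL_BY_CLASS = {"crossbred": 0.60, "indicus": 0.53}

SpeciesClass = str  # "crossbred" (B. taurus x B. indicus) or "indicus"
Sex = str  # "female" or "male"

_SPECIES_CLASSES = ("crossbred", "indicus")
_SEXES = ("female", "male")


class SchemaError(KeyError):
    """A required configuration field is missing or of the wrong shape."""


class ValidationError(ValueError):
    """A field value violates a domain invariant."""


def _require(mapping: dict, key: str, section: str):
    if key not in mapping:
        raise SchemaError(f"missing field '{key}' in section '{section}'")
    return mapping[key]


@dataclass(frozen=True)
class BreedParameters:
    """Genetic and biological constants of one breed and sex.

    ``max_attainable_weight`` is the genetic maximum body weight; the mature
    weight actually reached under (sub-)tropical feeding is taken as 90% of
    it.  ``min_mature_weight`` is the lower bound of the breed's body-weight
    envelope used by the condition index.  ``kl`` is the partial efficiency
    of ME use for lactation (0.60 for B. taurus x B. indicus crossbreds,
    0.53 for B. indicus breeds).
    """

    name: str
    species_class: SpeciesClass
    sex: Sex
    birth_weight: float  # kg
    max_attainable_weight: float  # kg, genetic maximum
    min_mature_weight: float  # kg, lower envelope bound
    peak_milk_yield: float  # kg/animal/day
    peak_month: float  # month of lactation at which the peak occurs
    lactation_length: float  # months
    milk_fat: float  # g/kg milk
    milk_protein: float  # g/kg milk
    gompertz_mu0: float = 0.015  # 1/day, initial relative growth rate
    max_daily_gain: float = 1.2  # kg/day, ceiling on potential growth
    kl: float | None = None  # defaults from species_class

    def __post_init__(self):
        if self.species_class not in _SPECIES_CLASSES:
            raise ValidationError(
                f"species_class must be one of {_SPECIES_CLASSES}, "
                f"got {self.species_class!r}"
            )
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.kl is None:
            object.__setattr__(self, "kl", KL_BY_CLASS[self.species_class])
        if not 0 < self.birth_weight < self.min_mature_weight < self.max_attainable_weight:
            raise ValidationError(
                "require 0 < birth_weight < min_mature_weight < "
                f"max_attainable_weight, got {self.birth_weight}, "
                f"{self.min_mature_weight}, {self.max_attainable_weight}"
            )
        if not 0 < self.gompertz_mu0 <= 0.1:
            raise ValidationError(f"gompertz_mu0 out of (0, 0.1]: {self.gompertz_mu0}")
        if not 1 <= self.peak_month <= self.lactation_length:
            raise ValidationError(
                f"peak_month {self.peak_month} outside [1, lactation_length="
                f"{self.lactation_length}]"
            )
        if self.peak_milk_yield <= 0:
            raise ValidationError(f"peak_milk_yield must be > 0: {self.peak_milk_yield}")
        if self.max_daily_gain <= 0:
            raise ValidationError(f"max_daily_gain must be > 0: {self.max_daily_gain}")
        if not 0 < self.kl <= 1:
            raise ValidationError(f"kl out of (0, 1]: {self.kl}")

    @property
    def final_weight(self) -> float:
        """Mature body weight under (sub-)tropical feeding: 0.9 x genetic max."""
        return 0.9 * self.max_attainable_weight


@dataclass
class AnimalState:
    """One animal's time-varying state.

    ``lactation_month`` counts months since calving, 1-based; 0 means the
    animal is dry.  ``gestation_day`` counts days since conception; 0 means
    not pregnant.
    """

    age: float  # years
    body_weight: float  # kg
    lactation_month: float = 0.0
    gestation_day: float = 0.0
    parity: int = 0

    def validate(self, lactation_length: float | None = None) -> "AnimalState":
        if self.body_weight <= 0:
            raise ValidationError(f"body_weight must be > 0: {self.body_weight}")
        if self.age < 0:
            raise ValidationError(f"age must be >= 0: {self.age}")
        if self.lactation_month < 0:
            raise ValidationError(f"lactation_month must be >= 0: {self.lactation_month}")
        if lactation_length is not None and self.lactation_month > lactation_length:
            raise ValidationError(
                f"lactation_month {self.lactation_month} exceeds lactation "
                f"length {lactation_length}"
            )
        if not 0 <= self.gestation_day <= 283:
            raise ValidationError(f"gestation_day out of [0, 283]: {self.gestation_day}")
        return self


@dataclass(frozen=True)
class Ration:
    """A diet's nutrient concentrations and the daily allowance.

    ``offered_dm`` is the feed on offer in kg DM/animal/day; ``inf`` means
    ad-libitum feeding.  ``ndf`` is in kg/kg DM (i.e. 550 g/kg DM -> 0.55).
    """

    dm: float  # g/kg as fed
    me: float  # MJ/kg DM
    ndf: float  # kg/kg DM
    cp: float  # g/kg DM
    contains_concentrate: bool = False
    offered_dm: float = math.inf  # kg DM/animal/day

    def __post_init__(self):
        if not 0 < self.ndf < 1:
            raise ValidationError(f"ndf must lie in (0, 1) kg/kg DM: {self.ndf}")
        if self.me <= 0:
            raise ValidationError(f"me must be > 0: {self.me}")
        if self.dm <= 0:
            raise ValidationError(f"dm must be > 0: {self.dm}")
        if self.cp < 0:
            raise ValidationError(f"cp must be >= 0: {self.cp}")
        if self.offered_dm <= 0:
            raise ValidationError(f"offered_dm must be > 0: {self.offered_dm}")


@dataclass
class Scenario:
    """A complete simulation setup: breed, animal, ration and run settings."""

    breed: BreedParameters
    initial_state: AnimalState
    ration: Ration
    n_steps: int
    horizontal_distance: float = 0.0  # m/day walked on the flat
    vertical_distance: float = 0.0  # m/day climbed
    days_per_step: float = 30.4  # days in one monthly time step

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValidationError(f"n_steps must be >= 1: {self.n_steps}")
        if self.horizontal_distance < 0 or self.vertical_distance < 0:
            raise ValidationError("activity distances must be >= 0")
        if self.days_per_step <= 0:
            raise ValidationError(f"days_per_step must be > 0: {self.days_per_step}")
        self.initial_state.validate(self.breed.lactation_length)


# ---------------------------------------------------------------------------
# YAML (de)serialisation


def _scenario_from_mapping(doc: dict) -> Scenario:
    if not isinstance(doc, dict):
        raise SchemaError("scenario file must contain a mapping at top level")
    for section in ("breed", "animal", "ration", "simulation"):
        if section not in doc:
            raise SchemaError(f"missing section '{section}'")

    b = doc["breed"]
    breed = BreedParameters(
        name=_require(b, "name", "breed"),
        species_class=_require(b, "species_class", "breed"),
        sex=_require(b, "sex", "breed"),
        birth_weight=float(_require(b, "birth_weight", "breed")),
        max_attainable_weight=float(_require(b, "max_attainable_weight", "breed")),
        min_mature_weight=float(_require(b, "min_mature_weight", "breed")),
        peak_milk_yield=float(_require(b, "peak_milk_yield", "breed")),
        peak_month=float(_require(b, "peak_month", "breed")),
        lactation_length=float(_require(b, "lactation_length", "breed")),
        milk_fat=float(_require(b, "milk_fat", "breed")),
        milk_protein=float(_require(b, "milk_protein", "breed")),
        gompertz_mu0=float(b.get("gompertz_mu0", 0.015)),
        max_daily_gain=float(b.get("max_daily_gain", 1.2)),
        kl=float(b["kl"]) if "kl" in b else None,
    )

    a = doc["animal"]
    state = AnimalState(
        age=float(_require(a, "age", "animal")),
        body_weight=float(_require(a, "body_weight", "animal")),
        lactation_month=float(a.get("lactation_month", 0.0)),
        gestation_day=float(a.get("gestation_day", 0.0)),
        parity=int(a.get("parity", 0)),
    )

    r = doc["ration"]
    offered = r.get("offered_dm", math.inf)
    if isinstance(offered, str) and offered.lower() in ("ad_libitum", "inf", ".inf"):
        offered = math.inf
    ration = Ration(
        dm=float(_require(r, "dm", "ration")),
        me=float(_require(r, "me", "ration")),
        ndf=float(_require(r, "ndf", "ration")),
        cp=float(_require(r, "cp", "ration")),
        contains_concentrate=bool(r.get("contains_concentrate", False)),
        offered_dm=float(offered),
    )

    s = doc["simulation"]
    return Scenario(
        breed=breed,
        initial_state=state,
        ration=ration,
        n_steps=int(_require(s, "n_steps", "simulation")),
        horizontal_distance=float(s.get("horizontal_distance", 0.0)),
        vertical_distance=float(s.get("vertical_distance", 0.0)),
        days_per_step=float(s.get("days_per_step", 30.4)),
    )


def _scenario_to_mapping(sc: Scenario) -> dict:
    breed = asdict(sc.breed)
    animal = asdict(sc.initial_state)
    ration = asdict(sc.ration)
    if math.isinf(ration["offered_dm"]):
        ration["offered_dm"] = "ad_libitum"
    return {
        "breed": breed,
        "animal": animal,
        "ration": ration,
        "simulation": {
            "n_steps": sc.n_steps,
            "horizontal_distance": sc.horizontal_distance,
            "vertical_distance": sc.vertical_distance,
            "days_per_step": sc.days_per_step,
        },
    }


def read_scenario(path: Union[str, Path]) -> Scenario:
    """Read and fully validate a scenario from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _scenario_from_mapping(doc)


def write_scenario(scenario: Scenario, path: Union[str, Path]) -> None:
    """Write a scenario to a YAML file (round-trips through read_scenario)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_scenario_to_mapping(scenario), fh, sort_keys=False)


FIXTURE_NAMES = ("maize_lablab", "oats_vetch")


def builtin_fixture(name: str) -> Scenario:
    """Return one of the two bundled stall-fed evaluation scenarios.

    ``maize_lablab``: cows fed maize-lablab stover ad libitum.
    ``oats_vetch``: cows fed oats-vetch hay ad libitum.
    """
    if name not in FIXTURE_NAMES:
        raise LookupError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("stallsim.data").joinpath(f"{name}.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _scenario_from_mapping(doc)
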