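import math

import pytest

from stallsim.core import AnimalState, BreedParameters, Ration, Scenario


@pytest.fixture
def crossbred_cow() -> BreedParameters:
    """A generic crossbred dairy cow breed for unit tests.

    Genetic maximum 500 kg gives a mature weight BWf = 450 kg, matching the
    hand-worked growth-curve examples.
    """
    return BreedParameters(
        name="test-crossbred",
        species_class="crossbred",
        sex="female",
        birth_weight=30.0,
        max_attainable_weight=500.0,
        min_mature_weight=250.0,
        peak_milk_yield=20.0,
        peak_month=2,
        lactation_length=10,
        milk_fat=46.3,
        milk_protein=29.0,
    )


@pytest.fixture
def forage_ration() -> Ration:
    return Ration(dm=890.0, me=9.4, ndf=0.55, cp=93.1, contains_concentrate=False)


@pytest.fixture
def lactating_state() -> AnimalState:
    return AnimalState(age=5.2, body_weight=415.0, lactation_month=1, parity=3)


@pytest.fixture
def basic_scenario(crossbred_cow, lactating_state, forage_ration) -> Scenario:
    return Scenario(
        breed=crossbred_cow,
        initial_state=lactating_state,
        ration=forage_ration,
        n_steps=5,
    )
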