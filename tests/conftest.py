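"""Shared fixtures: a hand-auditable two-food toy diet and seeded
synthetic surveys of several sizes."""

from __future__ import annotations

import numpy as np
import pytest

from protswap.domain import (
    IAA_KEYS,
    CompositionTable,
    DietRecord,
    FoodItem,
    Individual,
)
from protswap.intake import usual_intakes
from protswap.screening import screen
from protswap.synthetic import (
    SurveyConfig,
    generate_composition,
    generate_population,
)


def make_food(food_id, group, protein, kcal, af, lys=50.0, alc=0.0,
              substitutable=None, **iaa_overrides):
    """FoodItem with a plausible IAA profile; only lysine usually matters."""
    profile = {"his": 28.0, "ile": 45.0, "leu": 78.0, "lys": lys,
               "saa": 35.0, "aaa": 75.0, "thr": 40.0, "trp": 11.0,
               "val": 49.0}
    profile.update(iaa_overrides)
    if substitutable is None:
        substitutable = af > 0
    return FoodItem(
        food_id=food_id, name=food_id, group=group,
        protein_g_per_100g=protein, energy_kcal_per_100g=kcal,
        alcohol_kcal_per_100g=alc,
        iaa_mg_per_g_protein={k: profile[k] for k in IAA_KEYS},
        animal_protein_fraction=af, substitutable=substitutable)


@pytest.fixture(scope="session")
def toy_composition():
    """Beef (20 g protein, 200 kcal /100 g) + pasta (5 g protein,
    150 kcal /100 g): the hand-arithmetic substitution fixture."""
    return CompositionTable([
        make_food("beef", "red_meat", 20.0, 200.0, af=1.0, lys=90.0),
        make_food("pasta", "cereals", 5.0, 150.0, af=0.0, lys=28.0),
    ])


@pytest.fixture(scope="session")
def toy_individual():
    return Individual(individual_id="T1", sex="male", age_y=40.0,
                      weight_kg=70.0, height_cm=175.0, activity="moderate",
                      survey_weight=1.0)


@pytest.fixture(scope="session")
def toy_records():
    """Two identical days of the 200 g beef / 400 g pasta diet."""
    cons = (("beef", 200.0), ("pasta", 400.0))
    return [DietRecord("T1", d, cons) for d in (1, 2)]


@pytest.fixture(scope="session")
def small_survey():
    """n = 60 synthetic survey, screened, for fast structural tests."""
    cfg = SurveyConfig(n_individuals=60)
    comp = generate_composition(cfg)
    individuals, records = generate_population(cfg, comp, seed=11)
    individuals, records, _ = screen(individuals, records, comp)
    return cfg, comp, individuals, records


@pytest.fixture(scope="session")
def small_usual(small_survey):
    cfg, comp, individuals, records = small_survey
    usual, diagnostics = usual_intakes(records, individuals, comp)
    return usual, diagnostics


@pytest.fixture(scope="session")
def default_survey():
    """Full-size (n = 1678) synthetic survey at the default conditions."""
    cfg = SurveyConfig()
    comp = generate_composition(cfg)
    individuals, records = generate_population(cfg, comp, seed=1)
    individuals, records, report = screen(individuals, records, comp)
    return cfg, comp, individuals, records, report


@pytest.fixture(scope="session")
def default_usual(default_survey):
    cfg, comp, individuals, records, _ = default_survey
    usual, diagnostics = usual_intakes(records, individuals, comp)
    return usual, diagnostics
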