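"""Shared domain types for the dietary survey pipeline.

Units are fixed package-wide:

* food composition: g protein / 100 g food, kcal / 100 g food,
  mg amino acid / g protein;
* daily intakes: g/day (protein), kcal/day (energy), mg/day (amino acids);
* requirements and per-kg intakes: g/kg body weight/day (protein),
  mg/kg body weight/day (amino acids).

All unit conversions happen here or in :mod:`protswap.intake`; downstream
modules only ever see these units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

#: The nine indispensable amino acids, with the sulfur amino acids
#: (methionine + cysteine, ``saa``) and the aromatic amino acids
#: (phenylalanine + tyrosine, ``aaa``) pooled, matching how average
#: requirements are defined.
IAA_KEYS: tuple[str, ...] = (
    "his", "ile", "leu", "lys", "saa", "aaa", "thr", "trp", "val",
)

#: Food groups used for contribution tables; mirrors the animal/plant
#: grouping of a national food-consumption survey.
ANIMAL_GROUPS: tuple[str, ...] = (
    "red_meat", "poultry", "game", "offal", "delicatessen", "fish",
    "milk", "yogurt", "cheese", "other_dairy", "eggs",
)
PLANT_GROUPS: tuple[str, ...] = (
    "cereals", "potatoes", "fruit", "vegetables", "nuts_seeds", "legumes",
    "other_plant", "seasonings",
)
FOOD_GROUPS: tuple[str, ...] = ANIMAL_GROUPS + PLANT_GROUPS

#: Groups forming the legumes/nuts/seeds substitution mix.
LNS_GROUPS: tuple[str, ...] = ("legumes", "nuts_seeds")

SEXES: tuple[str, ...] = ("male", "female")
ACTIVITY_LEVELS: tuple[str, ...] = ("low", "moderate", "high")


class DomainError(ValueError):
    """Invalid domain object or file content."""


@dataclass(frozen=True)
class FoodItem:
    """One food of the composition table.

    ``animal_protein_fraction`` is the share of the food's protein that is
    animal-sourced (1 for meat, 0 for plain plant foods, intermediate for
    mixed dishes whose recipe combines both). ``substitutable`` marks foods
    whose animal protein the substitution simulator may remove; animal
    protein embedded in mixed dishes is typically not substitutable.
    """

    food_id: str
    name: str
    group: str
    protein_g_per_100g: float
    energy_kcal_per_100g: float
    alcohol_kcal_per_100g: float
    iaa_mg_per_g_protein: Mapping[str, float]
    animal_protein_fraction: float
    substitutable: bool = True

    def __post_init__(self) -> None:
        if self.group not in FOOD_GROUPS:
            raise DomainError(f"food {self.food_id!r}: unknown group {self.group!r}")
        for attr in ("protein_g_per_100g", "energy_kcal_per_100g",
                     "alcohol_kcal_per_100g"):
            if getattr(self, attr) < 0:
                raise DomainError(f"food {self.food_id!r}: {attr} must be >= 0")
        if self.protein_g_per_100g > 100:
            raise DomainError(
                f"food {self.food_id!r}: protein_g_per_100g > 100")
        if not 0.0 <= self.animal_protein_fraction <= 1.0:
            raise DomainError(
                f"food {self.food_id!r}: animal_protein_fraction "
                f"{self.animal_protein_fraction} outside [0, 1]")
        missing = set(IAA_KEYS) - set(self.iaa_mg_per_g_protein)
        if missing:
            raise DomainError(
                f"food {self.food_id!r}: missing IAA keys {sorted(missing)}")
        for key in IAA_KEYS:
            v = self.iaa_mg_per_g_protein[key]
            if not 0.0 <= v <= 1000.0:
                raise DomainError(
                    f"food {self.food_id!r}: iaa_{key} = {v} outside [0, 1000]")


@dataclass(frozen=True)
class Individual:
    """Survey participant with anthropometry and sampling weight."""

    individual_id: str
    sex: str
    age_y: float
    weight_kg: float
    height_cm: float
    activity: str
    survey_weight: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"{self.individual_id}: unknown sex {self.sex!r}")
        if self.activity not in ACTIVITY_LEVELS:
            raise DomainError(
                f"{self.individual_id}: unknown activity {self.activity!r}")
        if self.weight_kg <= 0:
            raise DomainError(f"{self.individual_id}: weight_kg must be > 0")
        if self.height_cm <= 0:
            raise DomainError(f"{self.individual_id}: height_cm must be > 0")
        if self.survey_weight <= 0:
            raise DomainError(f"{self.individual_id}: survey_weight must be > 0")

    @property
    def bmi(self) -> float:
        h = self.height_cm / 100.0
        return self.weight_kg / (h * h)


@dataclass(frozen=True)
class DietRecord:
    """One individual-day list of (food_id, grams consumed)."""

    individual_id: str
    day_index: int
    consumptions: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise DomainError(
                f"{self.individual_id}: day_index must be >= 1")
        for food_id, grams in self.consumptions:
            if grams < 0:
                raise DomainError(
                    f"{self.individual_id} day {self.day_index}: "
                    f"negative grams for {food_id!r}")


@dataclass(frozen=True)
class NutrientVector:
    """Daily nutrient totals; plant parts already carry any digestibility
    penalty, so ``protein_g == plant_protein_g + animal_protein_g`` holds on
    the penalized scale."""

    protein_g: float
    energy_kcal_noalc: float
    plant_protein_g: float
    animal_protein_g: float
    iaa_mg: Mapping[str, float]

    def __post_init__(self) -> None:
        total = self.plant_protein_g + self.animal_protein_g
        scale = max(abs(self.protein_g), abs(total), 1e-300)
        if abs(self.protein_g - total) > 1e-9 * scale:
            raise DomainError(
                "protein_g must equal plant_protein_g + animal_protein_g "
                f"({self.protein_g} vs {total})")
        for name in ("protein_g", "energy_kcal_noalc",
                     "plant_protein_g", "animal_protein_g"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def plant_share(self) -> float:
        """Fraction of (penalized) protein that is plant-sourced."""
        if self.protein_g == 0:
            return 0.0
        return self.plant_protein_g / self.protein_g


@dataclass(frozen=True)
class EARTable:
    """Estimated average requirements.

    Protein in g/kg body weight/day, amino acids in mg/kg body weight/day;
    ``cv`` is the coefficient of variation of the individual requirement
    around the EAR used by the probability approach.
    """

    protein_ear_g_per_kg: float = 0.66
    iaa_ear_mg_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {
            "his": 10.0, "ile": 20.0, "leu": 39.0, "lys": 30.0,
            "saa": 15.0, "aaa": 25.0, "thr": 15.0, "trp": 4.0, "val": 26.0,
        })
    cv: float = 0.125

    def __post_init__(self) -> None:
        if self.protein_ear_g_per_kg <= 0:
            raise DomainError("protein EAR must be > 0")
        for key in IAA_KEYS:
            if self.iaa_ear_mg_per_kg.get(key, 0.0) <= 0:
                raise DomainError(f"EAR for {key} must be > 0")
        if not 0.0 < self.cv < 1.0:
            raise DomainError("requirement CV must lie in (0, 1)")

    def ear(self, nutrient: str) -> float:
        """EAR for ``'protein'`` or one of the nine IAA keys."""
        if nutrient == "protein":
            return self.protein_ear_g_per_kg
        if nutrient in IAA_KEYS:
            return self.iaa_ear_mg_per_kg[nutrient]
        raise KeyError(nutrient)


class CompositionTable:
    """Ordered collection of :class:`FoodItem`, keyed by ``food_id``.

    Exposes dense numpy views (per-gram densities, IAA matrix, masks) used
    by the vectorised intake and substitution code. Food order is the
    insertion order and defines the column order of every matrix.
    """

    def __init__(self, foods: Iterable[FoodItem]):
        self._foods: dict[str, FoodItem] = {}
        for food in foods:
            if food.food_id in self._foods:
                raise DomainError(f"duplicate food_id {food.food_id!r}")
            self._foods[food.food_id] = food
        if not self._foods:
            raise DomainError("composition table is empty")
        self.food_ids: tuple[str, ...] = tuple(self._foods)
        self.index: dict[str, int] = {
            fid: i for i, fid in enumerate(self.food_ids)}
        items = list(self._foods.values())
        # per-gram densities
        self.protein_per_g = np.array(
            [f.protein_g_per_100g / 100.0 for f in items])
        self.energy_per_g = np.array(
            [f.energy_kcal_per_100g / 100.0 for f in items])
        self.alcohol_per_g = np.array(
            [f.alcohol_kcal_per_100g / 100.0 for f in items])
        self.animal_fraction = np.array(
            [f.animal_protein_fraction for f in items])
        self.substitutable = np.array([f.substitutable for f in items])
        self.groups = np.array([f.group for f in items])
        # IAA matrix, mg per g protein: shape (n_foods, 9)
        self.iaa_per_g_protein = np.array(
            [[f.iaa_mg_per_g_protein[k] for k in IAA_KEYS] for f in items])

    def __len__(self) -> int:
        return len(self._foods)

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self._foods.values())

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._foods

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._foods[food_id]
        except KeyError:
            raise DomainError(f"unknown food_id {food_id!r}") from None

    def pattern_vector(self, consumptions: Iterable[tuple[str, float]]
                       ) -> np.ndarray:
        """Dense grams-per-food vector in table order, summing duplicates."""
        vec = np.zeros(len(self))
        for food_id, grams in consumptions:
            try:
                vec[self.index[food_id]] += grams
            except KeyError:
                raise DomainError(f"unknown food_id {food_id!r}") from None
        return vec
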