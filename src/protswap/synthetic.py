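"""Synthetic dietary survey with the structure the analysis assumes.

The generator emulates a 7-day food-record survey of French-style adult
diets: ~69% of protein from animal sources, cereals dominating plant
protein, cereal protein poor in lysine and low in protein:energy relative
to meat and legumes. Its defaults are the study conditions of the
downstream analysis: 1678 adults (717 men / 961 women), mean protein
intake 1.34 (men) and 1.25 (women) g/kg body weight/day measured on the
penalized scale, 31% plant protein, cereals 67% of plant protein, meat 59%
(men) / 51% (women) of animal protein, and 5% of animal protein embedded
in mixed dishes and therefore untouchable by the substitution simulator.

Each individual receives a mean daily food pattern built analytically to
hit their drawn protein level and plant share exactly; energy closes onto
BMR x PAL through protein-free foods (oil, soft drink). Daily records are
the mean pattern times one lognormal day factor (mean 1), independent
across days.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .domain import (
    CompositionTable,
    DietRecord,
    DomainError,
    FoodItem,
    Individual,
)
from .io import write_composition_table, write_individuals, write_records
from .screening import henry_bmr


class ConfigError(DomainError):
    """Infeasible or inconsistent survey configuration."""


@dataclass(frozen=True)
class SurveyConfig:
    n_individuals: int = 1678
    sex_split: tuple[int, int] = (717, 961)  # (male, female) proportions
    n_days: int = 7
    target_plant_share: float = 0.31
    target_protein_g_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {"male": 1.34, "female": 1.25})
    cereal_share_of_plant: float = 0.67
    meat_share_of_animal: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.59, "female": 0.51})
    within_person_cv: float = 0.25
    between_person_cv: float = 0.20
    embedded_animal_fraction: float = 0.05
    plant_penalty: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if self.n_days < 2:
            raise ConfigError("n_days must be >= 2")
        for name in ("target_plant_share", "cereal_share_of_plant"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1)")
        for sex in ("male", "female"):
            if self.target_protein_g_per_kg[sex] <= 0:
                raise ConfigError("protein targets must be > 0")
            if not 0.0 < self.meat_share_of_animal[sex] < 1.0:
                raise ConfigError("meat_share_of_animal must lie in (0, 1)")
            if (self.meat_share_of_animal[sex]
                    + self.embedded_animal_fraction) >= 1.0:
                raise ConfigError(
                    "meat share + embedded fraction must stay below 1")
        if self.within_person_cv < 0 or self.between_person_cv <= 0:
            raise ConfigError("CVs must be positive "
                              "(within_person_cv may be 0 for testing)")
        if not 0.0 <= self.embedded_animal_fraction < 1.0:
            raise ConfigError("embedded_animal_fraction must lie in [0, 1)")
        if not 0.0 < self.plant_penalty <= 1.0:
            raise ConfigError("plant_penalty must lie in (0, 1]")

    @property
    def n_male(self) -> int:
        frac = self.sex_split[0] / sum(self.sex_split)
        return int(round(self.n_individuals * frac))


# ---------------------------------------------------------------------------
# Reference composition table
# ---------------------------------------------------------------------------

# IAA templates, mg per g protein (lysine set per food below).
_IAA_TEMPLATES = {
    "animal": {"his": 30, "ile": 47, "leu": 82, "saa": 36, "aaa": 73,
               "thr": 43, "trp": 12, "val": 51},
    "cereal": {"his": 22, "ile": 38, "leu": 70, "saa": 40, "aaa": 82,
               "thr": 29, "trp": 11, "val": 44},
    "legume": {"his": 27, "ile": 44, "leu": 77, "saa": 24, "aaa": 83,
               "thr": 38, "trp": 9, "val": 46},
    "nuts": {"his": 25, "ile": 40, "leu": 70, "saa": 35, "aaa": 80,
             "thr": 33, "trp": 12, "val": 48},
    "veg": {"his": 20, "ile": 38, "leu": 60, "saa": 28, "aaa": 65,
            "thr": 38, "trp": 11, "val": 48},
    "mixed": {"his": 26, "ile": 42, "leu": 76, "saa": 38, "aaa": 78,
              "thr": 36, "trp": 11, "val": 47},
    "zero": {k: 0 for k in ("his", "ile", "leu", "saa", "aaa",
                            "thr", "trp", "val")},
}

# id, name, group, template, protein g/100g, kcal/100g, alcohol kcal/100g,
# lysine mg/g protein, animal fraction, substitutable
_FOOD_DEFS: tuple[tuple, ...] = (
    ("beef", "Beef steak", "red_meat", "animal", 26.0, 170.0, 0.0, 90, 1.0, True),
    ("chicken", "Roast chicken", "poultry", "animal", 27.0, 150.0, 0.0, 85, 1.0, True),
    ("venison", "Venison", "game", "animal", 28.0, 145.0, 0.0, 88, 1.0, True),
    ("liver", "Calf liver", "offal", "animal", 20.0, 135.0, 0.0, 82, 1.0, True),
    ("ham", "Cooked ham", "delicatessen", "animal", 21.0, 190.0, 0.0, 84, 1.0, True),
    ("salmon", "Salmon fillet", "fish", "animal", 20.0, 180.0, 0.0, 92, 1.0, True),
    ("milk", "Semi-skimmed milk", "milk", "animal", 3.3, 47.0, 0.0, 80, 1.0, True),
    ("yogurt", "Plain yogurt", "yogurt", "animal", 4.0, 60.0, 0.0, 80, 1.0, True),
    ("cheese", "Emmental cheese", "cheese", "animal", 25.0, 380.0, 0.0, 75, 1.0, True),
    ("dairy_dessert", "Dairy dessert", "other_dairy", "animal", 4.0, 120.0, 0.0, 75, 1.0, True),
    ("eggs", "Eggs", "eggs", "animal", 12.5, 140.0, 0.0, 70, 1.0, True),
    ("pasta", "Cooked pasta", "cereals", "cereal", 5.0, 130.0, 0.0, 28, 0.0, False),
    ("bread", "Baguette", "cereals", "cereal", 9.0, 250.0, 0.0, 27, 0.0, False),
    ("rice", "Cooked rice", "cereals", "cereal", 4.0, 110.0, 0.0, 32, 0.0, False),
    ("potato", "Boiled potato", "potatoes", "veg", 2.0, 85.0, 0.0, 55, 0.0, False),
    ("apple", "Apple", "fruit", "veg", 0.3, 52.0, 0.0, 40, 0.0, False),
    ("vegetables", "Mixed vegetables", "vegetables", "veg", 2.0, 35.0, 0.0, 50, 0.0, False),
    ("almonds", "Almonds", "nuts_seeds", "nuts", 21.0, 600.0, 0.0, 32, 0.0, False),
    ("sunflower_seeds", "Sunflower seeds", "nuts_seeds", "nuts", 20.0, 580.0, 0.0, 36, 0.0, False),
    ("lentils", "Cooked lentils", "legumes", "legume", 9.0, 120.0, 0.0, 70, 0.0, False),
    ("chickpeas", "Cooked chickpeas", "legumes", "legume", 8.5, 130.0, 0.0, 67, 0.0, False),
    ("soy_dessert", "Soy dessert", "other_plant", "legume", 3.5, 80.0, 0.0, 62, 0.0, False),
    ("mustard", "Mustard", "seasonings", "veg", 5.0, 120.0, 0.0, 55, 0.0, False),
    ("olive_oil", "Olive oil", "seasonings", "zero", 0.0, 900.0, 0.0, 0, 0.0, False),
    ("soda", "Soft drink", "other_plant", "zero", 0.0, 41.0, 0.0, 0, 0.0, False),
    ("wine", "Red wine", "other_plant", "zero", 0.2, 8.0, 65.0, 0, 0.0, False),
    ("lasagna", "Lasagna (mixed dish)", "other_plant", "mixed", 7.0, 160.0, 0.0, 59, 0.5, False),
)


def generate_composition(config: SurveyConfig = SurveyConfig(),
                         seed: int | None = None) -> CompositionTable:
    """Reference composition table of 27 foods spanning all food groups.

    The table is a curated constant (the ``seed`` argument is accepted for
    interface symmetry with the population generator): cereals sit near
    15% protein:energy with lysine ~28-32 mg/g protein, red meat at ~61%
    protein:energy with lysine 90 mg/g protein, legumes at 26-30%
    protein:energy with lysine ~70 mg/g protein. Animal foods carry
    ``animal_protein_fraction`` 1, plant foods 0, and one mixed dish
    (lasagna) an intermediate, non-substitutable fraction.
    """
    foods = []
    for (fid, name, group, template, prot, kcal, alc, lys, af,
         subst) in _FOOD_DEFS:
        iaa = dict(_IAA_TEMPLATES[template])
        iaa["lys"] = lys
        foods.append(FoodItem(
            food_id=fid, name=name, group=group,
            protein_g_per_100g=prot, energy_kcal_per_100g=kcal,
            alcohol_kcal_per_100g=alc, iaa_mg_per_g_protein=iaa,
            animal_protein_fraction=af, substitutable=subst))
    return CompositionTable(foods)


# Population-level allocation shares (jittered per individual).
_MEAT_SPLIT = {"beef": 0.478, "chicken": 0.264, "venison": 0.010,
               "liver": 0.020, "ham": 0.228}
_NONMEAT_SPLIT = {"salmon": 0.155, "milk": 0.170, "yogurt": 0.115,
                  "cheese": 0.400, "dairy_dessert": 0.020, "eggs": 0.140}
_CEREAL_SPLIT = {"pasta": 0.40, "bread": 0.42, "rice": 0.18}
_NONCEREAL_SPLIT = {"potato": 0.18, "apple": 0.15, "vegetables": 0.24,
                    "almonds": 0.04, "sunflower_seeds": 0.017,
                    "lentils": 0.08, "chickpeas": 0.06,
                    "soy_dessert": 0.19, "mustard": 0.043}

_PAL = {"low": 1.4, "moderate": 1.6, "high": 1.8}


def _lognormal_mean1(rng: np.random.Generator, cv: float, size=None):
    """Lognormal draws with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def _jittered_shares(rng: np.random.Generator, shares: Mapping[str, float],
                     cv: float = 0.25) -> dict[str, float]:
    keys = list(shares)
    raw = np.array([shares[k] for k in keys]) * _lognormal_mean1(
        rng, cv, size=len(keys))
    raw /= raw.sum()
    return dict(zip(keys, raw))


def _check_feasible(config: SurveyConfig,
                    composition: CompositionTable) -> None:
    needed = ({"lasagna", "olive_oil", "soda", "wine"}
              | set(_MEAT_SPLIT) | set(_NONMEAT_SPLIT)
              | set(_CEREAL_SPLIT) | set(_NONCEREAL_SPLIT))
    missing = [fid for fid in sorted(needed) if fid not in composition]
    if missing:
        raise ConfigError(
            f"composition table lacks generator foods: {missing}")
    plant_protein_foods = [
        f for f in composition
        if f.animal_protein_fraction == 0 and f.protein_g_per_100g > 0]
    if not plant_protein_foods:
        raise ConfigError(
            "target plant share unattainable: no pure plant food with "
            "protein in the composition table")


def generate_population(
    config: SurveyConfig,
    composition: CompositionTable,
    seed: int | None = None,
) -> tuple[list[Individual], list[DietRecord]]:
    """Draw individuals and their daily food records.

    Deterministic for a fixed seed (default ``config.rng_seed``).
    """
    _check_feasible(config, composition)
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    n = config.n_individuals
    n_male = config.n_male

    # analytic bias correction so the logit-normal plant share hits its
    # target mean to first order
    logit_sd = 0.33
    pt = config.target_plant_share
    adj = pt - 0.5 * logit_sd ** 2 * pt * (1 - pt) * (1 - 2 * pt)
    logit_mu = np.log(adj / (1 - adj))

    individuals: list[Individual] = []
    records: list[DietRecord] = []
    width = len(str(n))
    for i in range(n):
        sex = "male" if i < n_male else "female"
        iid = f"I{i + 1:0{width}d}"
        age = float(rng.uniform(18.0, 64.99))
        if sex == "male":
            height = float(np.clip(rng.normal(175.6, 7.0), 155, 200))
        else:
            height = float(np.clip(rng.normal(162.5, 6.5), 145, 190))
        bmi = float(np.clip(rng.normal(24.5, 3.0), 18.5, 34.0))
        weight = bmi * (height / 100.0) ** 2
        activity = str(rng.choice(["low", "moderate", "high"],
                                  p=[0.35, 0.45, 0.20]))
        survey_weight = float(_lognormal_mean1(rng, 0.25))

        pal = _PAL[activity]
        bmr = henry_bmr(sex, age, weight, height, "weight_only")
        ei_total = bmr * pal * float(_lognormal_mean1(rng, 0.07))

        plant_share = float(np.clip(
            1.0 / (1.0 + np.exp(-(logit_mu + rng.normal(0, logit_sd)))),
            0.12, 0.60))
        # plant-heavy diets run slightly lower in protein per kg (the
        # plant foods consumed are poor in protein relative to energy):
        # about -4.5% protein per +10 percentage points of plant share
        tilt = 1.0 - 0.45 * (plant_share - config.target_plant_share)
        protein_gkg = (config.target_protein_g_per_kg[sex] * tilt
                       * float(_lognormal_mean1(
                           rng, config.between_person_cv)))
        p_pen = protein_gkg * weight  # penalized total protein, g/day

        pattern = _build_pattern(
            rng, config, composition, sex, p_pen, plant_share, ei_total)
        individuals.append(Individual(
            individual_id=iid, sex=sex, age_y=age, weight_kg=weight,
            height_cm=height, activity=activity,
            survey_weight=survey_weight))

        day_factors = _lognormal_mean1(rng, config.within_person_cv,
                                       size=config.n_days)
        for d in range(config.n_days):
            cons = tuple((fid, g * float(day_factors[d]))
                         for fid, g in pattern.items() if g > 0)
            records.append(DietRecord(
                individual_id=iid, day_index=d + 1, consumptions=cons))
    return individuals, records


def _build_pattern(rng, config: SurveyConfig,
                   composition: CompositionTable, sex: str,
                   p_pen: float, plant_share: float,
                   ei_total: float) -> dict[str, float]:
    """Mean daily grams per food hitting the individual's penalized protein
    total and plant share exactly, closing energy with protein-free foods."""
    pen = config.plant_penalty
    animal = (1.0 - plant_share) * p_pen
    plant_raw = plant_share * p_pen / pen

    grams: dict[str, float] = {}

    def protein_per_g(fid: str) -> float:
        return composition[fid].protein_g_per_100g / 100.0

    # embedded animal protein via the mixed dish
    e = config.embedded_animal_fraction
    lasagna_plant_raw = 0.0
    if e > 0:
        las = composition["lasagna"]
        las_animal = e * animal
        g_las = las_animal / (protein_per_g("lasagna")
                              * las.animal_protein_fraction)
        grams["lasagna"] = g_las
        lasagna_plant_raw = g_las * protein_per_g("lasagna") \
            * (1.0 - las.animal_protein_fraction)

    # animal foods: meat vs non-meat budgets, jittered splits
    meat_budget = config.meat_share_of_animal[sex] * animal
    nonmeat_budget = (1.0 - e) * animal - meat_budget
    for fid, share in _jittered_shares(rng, _MEAT_SPLIT).items():
        grams[fid] = meat_budget * share / protein_per_g(fid)
    for fid, share in _jittered_shares(rng, _NONMEAT_SPLIT).items():
        grams[fid] = nonmeat_budget * share / protein_per_g(fid)

    # plant foods: cereals get their share of *total* raw plant protein,
    # the mixed dish's plant part counts against the non-cereal remainder
    cereal_budget = config.cereal_share_of_plant * plant_raw
    noncereal_budget = plant_raw - cereal_budget - lasagna_plant_raw
    if noncereal_budget < 0:  # tiny plant share: shave the cereal budget
        cereal_budget = max(plant_raw - lasagna_plant_raw, 0.0)
        noncereal_budget = 0.0
    for fid, share in _jittered_shares(rng, _CEREAL_SPLIT).items():
        grams[fid] = cereal_budget * share / protein_per_g(fid)
    for fid, share in _jittered_shares(rng, _NONCEREAL_SPLIT).items():
        grams[fid] = noncereal_budget * share / protein_per_g(fid)

    # occasional wine (alcohol energy counts only toward screening)
    if rng.uniform() < 0.45:
        grams["wine"] = float(rng.uniform(50.0, 250.0))
        # keep the protein books exact: wine protein is plant protein, so
        # withdraw it from the vegetable budget
        wine_prot = grams["wine"] * protein_per_g("wine")
        grams["vegetables"] = max(
            0.0, grams.get("vegetables", 0.0)
            - wine_prot / protein_per_g("vegetables"))

    # energy closure with protein-free foods
    energy = sum(g * composition[f].energy_kcal_per_100g / 100.0
                 for f, g in grams.items())
    alcohol = sum(g * composition[f].alcohol_kcal_per_100g / 100.0
                  for f, g in grams.items())
    filler = max(0.0, ei_total - alcohol - energy)
    grams["olive_oil"] = 0.55 * filler / (
        composition["olive_oil"].energy_kcal_per_100g / 100.0)
    grams["soda"] = 0.45 * filler / (
        composition["soda"].energy_kcal_per_100g / 100.0)
    return grams


def generate_study(config: SurveyConfig, seed: int | None = None,
                   out_dir: str | os.PathLike = ".",
                   ) -> dict[str, str]:
    """Generate and serialize a full study bundle.

    Writes ``composition.csv``, ``individuals.csv``, ``records.csv`` and a
    ``manifest.json`` recording the config, seed and package version into
    ``out_dir``; regenerating with the same config and seed reproduces the
    files byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    used_seed = config.rng_seed if seed is None else seed
    composition = generate_composition(config, used_seed)
    individuals, records = generate_population(config, composition,
                                               used_seed)
    paths = {
        "composition": str(out / "composition.csv"),
        "individuals": str(out / "individuals.csv"),
        "records": str(out / "records.csv"),
        "manifest": str(out / "manifest.json"),
    }
    write_composition_table(composition, paths["composition"])
    write_individuals(individuals, paths["individuals"])
    write_records(records, paths["records"])
    manifest = {
        "config": _config_dict(config),
        "seed": used_seed,
        "package_version": __version__,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _config_dict(config: SurveyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sex_split"] = list(d["sex_split"])
    return d


def config_from_manifest(path: str | os.PathLike) -> tuple[SurveyConfig, int]:
    """Reload the (config, seed) pair recorded by :func:`generate_study`."""
    with open(path) as fh:
        manifest = json.load(fh)
    cfg = manifest["config"]
    cfg["sex_split"] = tuple(cfg["sex_split"])
    return SurveyConfig(**cfg), manifest["seed"]
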