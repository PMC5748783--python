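"""Readers and writers for the delimited-text exchange formats.

Schemas (all CSV with a header row):

* ``composition.csv`` — one row per food: ``food_id, name, group,
  protein_g_per_100g, energy_kcal_per_100g, alcohol_kcal_per_100g,
  animal_protein_fraction, substitutable, iaa_his .. iaa_val``.
* ``individuals.csv`` — ``individual_id, sex, age_y, weight_kg, height_cm,
  activity, survey_weight``.
* ``records.csv`` — long format: ``individual_id, day_index, food_id,
  grams``; alternatively a single long file that repeats the individual
  attribute columns on every row.

Numeric output uses 15 significant digits so a write/read round trip is
the identity to better than 1e-12 relative.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .domain import (
    IAA_KEYS,
    CompositionTable,
    DietRecord,
    DomainError,
    FoodItem,
    Individual,
)

FLOAT_FORMAT = "%.15g"

_COMPOSITION_COLUMNS = [
    "food_id", "name", "group", "protein_g_per_100g",
    "energy_kcal_per_100g", "alcohol_kcal_per_100g",
    "animal_protein_fraction", "substitutable",
] + [f"iaa_{k}" for k in IAA_KEYS]

_INDIVIDUAL_COLUMNS = [
    "individual_id", "sex", "age_y", "weight_kg", "height_cm",
    "activity", "survey_weight",
]

_RECORD_COLUMNS = ["individual_id", "day_index", "food_id", "grams"]


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing column(s) {missing}")


def read_composition_table(path: str | os.PathLike) -> CompositionTable:
    """Parse a composition CSV into a validated :class:`CompositionTable`.

    Raises :class:`DomainError` naming the offending row and column on any
    invariant violation (negative content, animal fraction outside [0, 1],
    duplicate food id, missing column).
    """
    df = pd.read_csv(path)
    _require_columns(df, _COMPOSITION_COLUMNS, str(path))
    foods = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            foods.append(FoodItem(
                food_id=str(rec["food_id"]),
                name=str(rec["name"]),
                group=str(rec["group"]),
                protein_g_per_100g=float(rec["protein_g_per_100g"]),
                energy_kcal_per_100g=float(rec["energy_kcal_per_100g"]),
                alcohol_kcal_per_100g=float(rec["alcohol_kcal_per_100g"]),
                animal_protein_fraction=float(rec["animal_protein_fraction"]),
                substitutable=_parse_bool(rec["substitutable"]),
                iaa_mg_per_g_protein={
                    k: float(rec[f"iaa_{k}"]) for k in IAA_KEYS},
            ))
        except DomainError as exc:
            raise DomainError(f"{path} row {row_no}: {exc}") from None
    return CompositionTable(foods)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise DomainError(f"cannot parse boolean {value!r}")


def write_composition_table(table: CompositionTable,
                            path: str | os.PathLike) -> None:
    rows = []
    for f in table:
        row = {
            "food_id": f.food_id, "name": f.name, "group": f.group,
            "protein_g_per_100g": f.protein_g_per_100g,
            "energy_kcal_per_100g": f.energy_kcal_per_100g,
            "alcohol_kcal_per_100g": f.alcohol_kcal_per_100g,
            "animal_protein_fraction": f.animal_protein_fraction,
            "substitutable": f.substitutable,
        }
        row.update({f"iaa_{k}": f.iaa_mg_per_g_protein[k] for k in IAA_KEYS})
        rows.append(row)
    pd.DataFrame(rows, columns=_COMPOSITION_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_diet_records(
    records_path: str | os.PathLike,
    individuals_path: str | os.PathLike | None = None,
    composition: CompositionTable | None = None,
) -> tuple[list[Individual], list[DietRecord]]:
    """Load a survey as ``(individuals, records)``.

    Two layouts are accepted: a pair of files (``individuals.csv`` +
    long-format ``records.csv``), or a single long file whose rows carry
    both the individual attributes and the day-level consumptions. When a
    ``composition`` table is given, every ``food_id`` is cross-validated
    against it.
    """
    df = pd.read_csv(records_path)
    if individuals_path is not None:
        ind_df = pd.read_csv(individuals_path)
        _require_columns(ind_df, _INDIVIDUAL_COLUMNS, str(individuals_path))
        _require_columns(df, _RECORD_COLUMNS, str(records_path))
    else:
        _require_columns(df, _INDIVIDUAL_COLUMNS + _RECORD_COLUMNS[1:],
                         str(records_path))
        ind_df = (df[_INDIVIDUAL_COLUMNS]
                  .drop_duplicates(subset="individual_id", keep="first"))

    individuals = []
    for row in ind_df.itertuples(index=False):
        rec = row._asdict()
        individuals.append(Individual(
            individual_id=str(rec["individual_id"]),
            sex=str(rec["sex"]),
            age_y=float(rec["age_y"]),
            weight_kg=float(rec["weight_kg"]),
            height_cm=float(rec["height_cm"]),
            activity=str(rec["activity"]),
            survey_weight=float(rec["survey_weight"]),
        ))
    known_ids = {ind.individual_id for ind in individuals}

    records = []
    grouped = df.groupby(["individual_id", "day_index"], sort=True)
    for (iid, day), chunk in grouped:
        iid = str(iid)
        if iid not in known_ids:
            raise DomainError(
                f"{records_path}: record for unknown individual {iid!r}")
        consumptions = []
        for food_id, grams in zip(chunk["food_id"], chunk["grams"]):
            grams = float(grams)
            if grams < 0:
                raise DomainError(
                    f"{records_path}: negative grams for individual {iid!r} "
                    f"day {day} food {food_id!r}")
            if composition is not None and str(food_id) not in composition:
                raise DomainError(
                    f"{records_path}: unknown food_id {food_id!r} "
                    f"(individual {iid!r} day {day})")
            consumptions.append((str(food_id), grams))
        records.append(DietRecord(
            individual_id=iid, day_index=int(day),
            consumptions=tuple(consumptions)))

    recorded = {r.individual_id for r in records}
    silent = known_ids - recorded
    if silent:
        raise DomainError(
            f"individual(s) without any recorded day: {sorted(silent)}")
    return individuals, records


def write_individuals(individuals: Sequence[Individual],
                      path: str | os.PathLike) -> None:
    rows = [{
        "individual_id": i.individual_id, "sex": i.sex, "age_y": i.age_y,
        "weight_kg": i.weight_kg, "height_cm": i.height_cm,
        "activity": i.activity, "survey_weight": i.survey_weight,
    } for i in individuals]
    pd.DataFrame(rows, columns=_INDIVIDUAL_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def write_records(records: Sequence[DietRecord],
                  path: str | os.PathLike) -> None:
    rows = []
    for r in records:
        for food_id, grams in r.consumptions:
            rows.append({"individual_id": r.individual_id,
                         "day_index": r.day_index,
                         "food_id": food_id, "grams": grams})
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def write_results(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any tabular pipeline output (simulation curves, prevalence or
    contribution tables) with a stable column order and full precision."""
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
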