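"""Sample screening: age window and Goldberg/Black energy misreporting.

Individuals older than the age ceiling are removed first (their reference
protein intake differs from the younger adult population). Among the
remainder, each individual's mean reported daily energy intake — alcohol
included, since misreporting concerns total energy — is compared to the
Henry-equation basal metabolic rate (BMR). Ratios outside the Goldberg
cut-offs for the individual's physical activity level (PAL) flag under- or
over-reporters, which are excluded.

The Goldberg cut-offs in Black's confidence-limit form are

    lower, upper = PAL * exp(-+ z * s / 100),
    s = sqrt(CV_wEI^2 / n_days + CV_wB^2 + CV_tP^2)

with the conventional constants CV_wEI = 23% (within-person variation of
energy intake), CV_wB = 8.5% (BMR prediction error) and CV_tP = 15%
(between-person PAL variation), z = 1.96.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .domain import CompositionTable, DietRecord, DomainError, Individual
from .intake import daily_intake_table


def _load_henry_table() -> dict:
    path = importlib.resources.files("protswap") / "data" / \
        "henry_coefficients.yaml"
    return yaml.safe_load(path.read_text())


_HENRY = _load_henry_table()
MJ_TO_KCAL: float = float(_HENRY["mj_to_kcal"])


def henry_bmr(sex: str, age_y: float, weight_kg: float,
              height_cm: float | None = None,
              variant: str = "weight_only") -> float:
    """Basal metabolic rate in kcal/day from the Henry coefficient table.

    ``variant`` selects the weight-only or the weight-and-height equation
    set. Supported adult bands span 18-70 years.
    """
    if variant not in ("weight_only", "weight_height"):
        raise DomainError(f"unknown Henry variant {variant!r}")
    if variant == "weight_height" and height_cm is None:
        raise DomainError("weight_height variant needs height_cm")
    try:
        bands = _HENRY[variant][sex]
    except KeyError:
        raise DomainError(f"unknown sex {sex!r}") from None
    last_max = bands[-1]["age_max"]
    for band in bands:
        in_band = band["age_min"] <= age_y < band["age_max"] or (
            band["age_max"] == last_max and age_y == last_max)
        if in_band:
            mj = band["w"] * weight_kg + band["c"]
            if variant == "weight_height":
                mj += band["h"] * (height_cm / 100.0)
            return mj * MJ_TO_KCAL
    raise DomainError(
        f"age {age_y} outside supported Henry bands "
        f"[{bands[0]['age_min']}, {last_max}]")


def goldberg_bounds(pal: float, n_days: int,
                    cv_energy_intake: float = 23.0,
                    cv_bmr: float = 8.5,
                    cv_pal: float = 15.0,
                    z: float = 1.96) -> tuple[float, float]:
    """(lower, upper) cut-offs on the EI:BMR ratio for one PAL."""
    if n_days < 1:
        raise DomainError("n_days must be >= 1")
    if pal <= 0:
        raise DomainError("pal must be > 0")
    s = np.sqrt(cv_energy_intake ** 2 / n_days + cv_bmr ** 2 + cv_pal ** 2)
    return (float(pal * np.exp(-z * s / 100.0)),
            float(pal * np.exp(z * s / 100.0)))


@dataclass(frozen=True)
class ScreeningConfig:
    age_min: float = 18.0
    age_max: float = 65.0  # exclusive above: age > age_max is excluded
    pal_by_activity: Mapping[str, float] = field(
        default_factory=lambda: {"low": 1.4, "moderate": 1.6, "high": 1.8})
    cv_energy_intake: float = 23.0
    cv_bmr: float = 8.5
    cv_pal: float = 15.0
    z: float = 1.96
    henry_variant: str = "weight_only"


@dataclass
class ScreeningReport:
    n_input: int
    n_age_excluded: int
    n_under_reporters: int
    n_over_reporters: int
    n_retained: int
    flags: pd.DataFrame  # per-individual ratio, bounds and decision

    def __post_init__(self) -> None:
        total = (self.n_age_excluded + self.n_under_reporters
                 + self.n_over_reporters + self.n_retained)
        if total != self.n_input:
            raise DomainError("screening counts do not add up")


def screen(individuals: Sequence[Individual],
           records: Sequence[DietRecord],
           composition: CompositionTable,
           config: ScreeningConfig = ScreeningConfig(),
           ) -> tuple[list[Individual], list[DietRecord], ScreeningReport]:
    """Apply age and misreporter exclusions; returns the retained
    individuals and their records plus a full report."""
    daily = daily_intake_table(records, composition)
    energy = (daily["energy_kcal_noalc"] + daily["energy_kcal_alcohol"]
              ).groupby(daily["individual_id"], sort=False)
    mean_energy = energy.mean()
    n_days = energy.size()
    if n_days.min() < 1:
        raise DomainError("individual with zero recorded days")

    rows = []
    retained_ids = set()
    n_age = n_under = n_over = 0
    for ind in individuals:
        if ind.individual_id not in mean_energy.index:
            raise DomainError(
                f"individual {ind.individual_id!r} has no recorded days")
        age_excluded = (ind.age_y < config.age_min
                        or ind.age_y > config.age_max)
        pal = config.pal_by_activity[ind.activity]
        bmr = henry_bmr(ind.sex, ind.age_y, ind.weight_kg, ind.height_cm,
                        config.henry_variant) if not age_excluded else np.nan
        d = int(n_days[ind.individual_id])
        lower, upper = goldberg_bounds(
            pal, d, config.cv_energy_intake, config.cv_bmr,
            config.cv_pal, config.z)
        ratio = float(mean_energy[ind.individual_id] / bmr) \
            if not age_excluded else np.nan
        under = over = False
        if age_excluded:
            n_age += 1
            status = "age_excluded"
        elif ratio < lower:
            under = True
            n_under += 1
            status = "under_reporter"
        elif ratio > upper:
            over = True
            n_over += 1
            status = "over_reporter"
        else:
            retained_ids.add(ind.individual_id)
            status = "retained"
        rows.append({
            "individual_id": ind.individual_id, "age_y": ind.age_y,
            "pal": pal, "n_days": d, "ei_bmr_ratio": ratio,
            "lower_cutoff": lower, "upper_cutoff": upper,
            "age_excluded": age_excluded, "under_reporter": under,
            "over_reporter": over, "status": status,
        })

    report = ScreeningReport(
        n_input=len(individuals), n_age_excluded=n_age,
        n_under_reporters=n_under, n_over_reporters=n_over,
        n_retained=len(retained_ids), flags=pd.DataFrame(rows))
    kept_individuals = [i for i in individuals
                        if i.individual_id in retained_ids]
    kept_records = [r for r in records if r.individual_id in retained_ids]
    return kept_individuals, kept_records, report
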