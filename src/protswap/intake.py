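"""Food records -> daily nutrient intakes -> usual intakes.

Two stages live here:

1. **Daily accounting** — grams of each food are converted to protein,
   non-alcohol energy and the nine indispensable amino acids (IAA), with
   each food's protein split into animal and plant parts by its
   ``animal_protein_fraction``. The plant part of protein *and* of every
   IAA is multiplied by a digestibility penalty (default 0.95, i.e., a 5%
   reduction accounting for the lower real ileal digestibility of plant
   protein) before anything downstream sees it.

2. **Usual-intake estimation** — a simplified Multiple-Source-Method
   estimator for nutrients consumed every day: per nutrient the pooled
   daily intakes are Box-Cox transformed (lambda fitted by profile
   likelihood on a grid), decomposed into between- and within-person
   variance by one-way ANOVA, each individual's mean is shrunk toward the
   population mean by the BLUP factor sigma2_b / (sigma2_b + sigma2_w / D_i),
   and the result is back-transformed with a second-order (half within-
   variance times second derivative) bias correction so that the estimate
   targets the long-run *mean* of daily intakes rather than the median.
   No covariates and no consumption-probability part are modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .domain import (
    IAA_KEYS,
    CompositionTable,
    DietRecord,
    DomainError,
    Individual,
    NutrientVector,
)

#: Column names of the daily/usual nutrient tables, in stable order.
NUTRIENT_COLUMNS: tuple[str, ...] = (
    "protein_g", "energy_kcal_noalc", "energy_kcal_alcohol",
    "plant_protein_g", "animal_protein_g",
) + tuple(f"iaa_{k}_mg" for k in IAA_KEYS)

#: Nutrients compared to per-kg requirements.
REQUIREMENT_NUTRIENTS: tuple[str, ...] = ("protein",) + IAA_KEYS


@dataclass(frozen=True)
class DigestibilityPolicy:
    """Multiplicative coefficient applied to plant-sourced protein and
    plant-sourced IAA (0.95 = 5% penalty)."""

    plant_penalty: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.plant_penalty <= 1.0:
            raise DomainError("plant_penalty must lie in (0, 1]")


def nutrient_arrays(patterns: np.ndarray, composition: CompositionTable,
                    policy: DigestibilityPolicy) -> dict[str, np.ndarray]:
    """Vectorised nutrient accounting.

    ``patterns`` is an (n, n_foods) grams matrix (or a single (n_foods,)
    vector) in composition order. Returns per-row totals; the plant parts
    are penalized, and ``protein`` = ``animal_protein`` + penalized
    ``plant_protein``.
    """
    P = np.atleast_2d(np.asarray(patterns, dtype=float))
    crude = P * composition.protein_per_g  # g protein per food
    animal = crude * composition.animal_fraction
    plant_raw = crude - animal
    plant_pen = plant_raw * policy.plant_penalty
    effective = animal + plant_pen  # penalized protein per food
    out = {
        "protein_g": effective.sum(axis=1),
        "energy_kcal_noalc": (P * composition.energy_per_g).sum(axis=1),
        "energy_kcal_alcohol": (P * composition.alcohol_per_g).sum(axis=1),
        "plant_protein_g": plant_pen.sum(axis=1),
        "animal_protein_g": animal.sum(axis=1),
        "crude_protein_g": crude.sum(axis=1),
    }
    iaa = effective @ composition.iaa_per_g_protein  # (n, 9) in mg
    for j, key in enumerate(IAA_KEYS):
        out[f"iaa_{key}_mg"] = iaa[:, j]
    return out


def daily_nutrients(record: DietRecord, composition: CompositionTable,
                    policy: DigestibilityPolicy = DigestibilityPolicy(),
                    ) -> NutrientVector:
    """Nutrient totals of one individual-day record."""
    vec = composition.pattern_vector(record.consumptions)
    arrays = nutrient_arrays(vec, composition, policy)
    return NutrientVector(
        protein_g=float(arrays["protein_g"][0]),
        energy_kcal_noalc=float(arrays["energy_kcal_noalc"][0]),
        plant_protein_g=float(arrays["plant_protein_g"][0]),
        animal_protein_g=float(arrays["animal_protein_g"][0]),
        iaa_mg={k: float(arrays[f"iaa_{k}_mg"][0]) for k in IAA_KEYS},
    )


def daily_intake_table(records: Sequence[DietRecord],
                       composition: CompositionTable,
                       policy: DigestibilityPolicy = DigestibilityPolicy(),
                       ) -> pd.DataFrame:
    """Long table of daily nutrient intakes, one row per individual-day."""
    ids, days, vecs = [], [], []
    for r in records:
        ids.append(r.individual_id)
        days.append(r.day_index)
        vecs.append(composition.pattern_vector(r.consumptions))
    arrays = nutrient_arrays(np.array(vecs), composition, policy)
    data = {"individual_id": ids, "day_index": days}
    for col in NUTRIENT_COLUMNS:
        data[col] = arrays[col]
    return pd.DataFrame(data)


def mean_patterns(records: Sequence[DietRecord],
                  composition: CompositionTable,
                  ) -> tuple[list[str], np.ndarray]:
    """Per-individual mean daily food pattern.

    Returns the individual ids (order of first appearance) and an
    (n_individuals, n_foods) grams matrix averaged over each individual's
    recorded days.
    """
    order: list[str] = []
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for r in records:
        if r.individual_id not in sums:
            order.append(r.individual_id)
            sums[r.individual_id] = np.zeros(len(composition))
            counts[r.individual_id] = 0
        sums[r.individual_id] += composition.pattern_vector(r.consumptions)
        counts[r.individual_id] += 1
    matrix = np.array([sums[i] / counts[i] for i in order])
    return order, matrix


# ---------------------------------------------------------------------------
# Usual-intake estimation
# ---------------------------------------------------------------------------

_LAMBDA_GRID = np.round(np.arange(-1.0, 2.0 + 1e-9, 0.1), 1)


@dataclass(frozen=True)
class ShrinkageDiagnostics:
    """Per-nutrient diagnostics of the usual-intake estimator, on the
    Box-Cox transformed scale."""

    box_cox_lambda: float
    var_between: float
    var_within: float
    degenerate: bool = False

    @property
    def variance_ratio(self) -> float:
        total = self.var_between + self.var_within
        return self.var_between / total if total > 0 else float("nan")


def fit_box_cox_lambda(values: np.ndarray) -> float:
    """Profile-likelihood Box-Cox lambda on a [-1, 2] grid (step 0.1).

    Ties (within 1e-9 of the maximum log-likelihood) break toward
    lambda = 1, i.e., no transformation. Non-positive data forces
    lambda = 1, since the power transform needs positive support.
    """
    x = np.asarray(values, dtype=float)
    if x.min() <= 0:
        return 1.0
    llf = np.array([stats.boxcox_llf(lmb, x) for lmb in _LAMBDA_GRID])
    best = llf.max()
    candidates = _LAMBDA_GRID[llf >= best - 1e-9 * max(1.0, abs(best))]
    if np.any(np.isclose(candidates, 1.0)):
        return 1.0
    # among ties, prefer the lambda closest to 1
    return float(candidates[np.argmin(np.abs(candidates - 1.0))])


def _box_cox(x: np.ndarray, lmb: float) -> np.ndarray:
    if lmb == 0.0:
        return np.log(x)
    return (np.power(x, lmb) - 1.0) / lmb


def _inv_box_cox_mean(t: np.ndarray, lmb: float,
                      var_within: float) -> np.ndarray:
    """Back-transform with second-order bias correction.

    For g the Box-Cox transform and T the transformed daily intake
    scattering with variance ``var_within`` around the individual's
    transformed usual value t, the long-run mean of daily intakes is
    approximately  g^{-1}(t) + 0.5 * (g^{-1})''(t) * var_within.
    """
    if lmb == 0.0:
        base = np.exp(t)
        second = base
    else:
        arg = np.maximum(lmb * t + 1.0, 1e-12)
        base = np.power(arg, 1.0 / lmb)
        second = (1.0 - lmb) * np.power(arg, 1.0 / lmb - 2.0)
    return base + 0.5 * second * var_within


def _variance_components(values: np.ndarray, groups: np.ndarray,
                         ) -> tuple[float, float, pd.Series, float]:
    """Unbalanced one-way ANOVA method-of-moments decomposition.

    Returns (var_between, var_within, per-group means, grand mean).
    """
    s = pd.Series(values)
    g = pd.Series(groups)
    means = s.groupby(g, sort=False).mean()
    sizes = s.groupby(g, sort=False).size()
    n_total = len(s)
    k = len(means)
    grand = float(s.mean())
    ssw = float(((s - means.reindex(g).to_numpy()) ** 2).sum())
    var_within = ssw / (n_total - k) if n_total > k else 0.0
    ssb = float((sizes * (means - grand) ** 2).sum())
    msb = ssb / (k - 1) if k > 1 else 0.0
    n0 = (n_total - float((sizes ** 2).sum()) / n_total) / (k - 1) \
        if k > 1 else 1.0
    var_between = max(0.0, (msb - var_within) / n0)
    return var_between, var_within, means, grand


def usual_intakes(
    records: Sequence[DietRecord],
    individuals: Sequence[Individual],
    composition: CompositionTable,
    policy: DigestibilityPolicy = DigestibilityPolicy(),
) -> tuple[pd.DataFrame, dict[str, ShrinkageDiagnostics]]:
    """Estimate usual nutrient intakes for every individual.

    Returns a DataFrame indexed by ``individual_id`` with per-day columns
    (``protein_g``, ``energy_kcal_noalc``, ``plant_protein_g``,
    ``animal_protein_g``, ``iaa_*_mg``) plus per-kg columns
    (``protein_g_perkg``, ``iaa_*_mg_perkg``), and the per-nutrient
    shrinkage diagnostics.
    """
    daily = daily_intake_table(records, composition, policy)
    day_counts = daily.groupby("individual_id", sort=False).size()
    if (day_counts < 2).any():
        few = day_counts[day_counts < 2].index.tolist()
        raise DomainError(
            f"usual-intake estimation needs >= 2 recorded days; "
            f"individual(s) {few} have fewer")

    groups = daily["individual_id"].to_numpy()
    usual = pd.DataFrame(index=pd.Index(day_counts.index,
                                        name="individual_id"))
    diagnostics: dict[str, ShrinkageDiagnostics] = {}
    for col in NUTRIENT_COLUMNS:
        if col == "energy_kcal_alcohol":
            continue  # alcohol energy only matters for screening
        values = daily[col].to_numpy(dtype=float)
        usual[col], diagnostics[col] = _usual_one_nutrient(values, groups,
                                                           day_counts)

    weights = pd.Series({i.individual_id: i.weight_kg for i in individuals})
    weights = weights.reindex(usual.index)
    if weights.isna().any():
        missing = usual.index[weights.isna()].tolist()
        raise DomainError(f"records for unknown individual(s): {missing}")
    usual["protein_g_perkg"] = usual["protein_g"] / weights
    for k in IAA_KEYS:
        usual[f"iaa_{k}_mg_perkg"] = usual[f"iaa_{k}_mg"] / weights
    return usual, diagnostics


def _usual_one_nutrient(values: np.ndarray, groups: np.ndarray,
                        day_counts: pd.Series,
                        ) -> tuple[pd.Series, ShrinkageDiagnostics]:
    if np.ptp(values) == 0.0 or np.var(values) < 1e-24 * (
            1.0 + np.mean(values) ** 2):
        warnings.warn("nutrient has (near-)zero variance across all "
                      "individual-days; returning individual means",
                      stacklevel=3)
        means = pd.Series(values).groupby(pd.Series(groups),
                                          sort=False).mean()
        return means.reindex(day_counts.index), ShrinkageDiagnostics(
            box_cox_lambda=1.0, var_between=0.0, var_within=0.0,
            degenerate=True)

    lmb = fit_box_cox_lambda(values)
    t = _box_cox(np.maximum(values, 1e-12), lmb) if lmb != 1.0 \
        else values - 1.0  # lambda=1 Box-Cox is x - 1; affine, harmless
    var_b, var_w, means_t, grand_t = _variance_components(t, groups)
    d = day_counts.reindex(means_t.index).to_numpy(dtype=float)
    if var_b + var_w == 0.0:
        shrink = np.ones_like(d)
    else:
        shrink = var_b / (var_b + var_w / d)
    t_usual = grand_t + shrink * (means_t.to_numpy() - grand_t)
    x_usual = _inv_box_cox_mean(t_usual, lmb, var_w) if lmb != 1.0 \
        else t_usual + 1.0
    x_usual = np.maximum(x_usual, 0.0)
    series = pd.Series(x_usual, index=means_t.index).reindex(day_counts.index)
    return series, ShrinkageDiagnostics(
        box_cox_lambda=lmb, var_between=var_b, var_within=var_w)


def usual_perkg_frame(usual: pd.DataFrame) -> pd.DataFrame:
    """Per-kg usual intakes of the requirement nutrients, columns named by
    nutrient key (``protein`` in g/kg/d, IAA in mg/kg/d)."""
    out = pd.DataFrame(index=usual.index)
    out["protein"] = usual["protein_g_perkg"]
    for k in IAA_KEYS:
        out[k] = usual[f"iaa_{k}_mg_perkg"]
    return out
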