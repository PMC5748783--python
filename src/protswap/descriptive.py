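"""Descriptive surfaces: food-group contribution tables and
intake-versus-plant-share regressions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .domain import (
    ANIMAL_GROUPS,
    PLANT_GROUPS,
    CompositionTable,
    DietRecord,
    DomainError,
    EARTable,
    Individual,
)
from .intake import DigestibilityPolicy, mean_patterns


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mean = float(np.average(x, weights=w))
    var = float(np.average((x - mean) ** 2, weights=w))
    return mean, float(np.sqrt(var))


def contribution_table(records: Sequence[DietRecord],
                       composition: CompositionTable,
                       individuals: Sequence[Individual],
                       policy: DigestibilityPolicy = DigestibilityPolicy(),
                       ) -> pd.DataFrame:
    """Percentage contribution of each food group to protein and lysine
    intake, weighted mean +- SD by sex.

    Contributions are computed per individual on the penalized scale (each
    food's protein is its animal part plus penalty-scaled plant part) and
    normalized to 100% within the individual before averaging. The
    ``animal`` and ``plant`` super-rows are the sums of their member
    groups.
    """
    ids, patterns = mean_patterns(records, composition)
    ind_by_id = {i.individual_id: i for i in individuals}
    missing = [i for i in ids if i not in ind_by_id]
    if missing:
        raise DomainError(f"records for unknown individual(s): {missing}")

    # per-food effective (penalized) protein and lysine, per individual
    crude = patterns * composition.protein_per_g
    effective = crude * (composition.animal_fraction
                         + policy.plant_penalty
                         * (1.0 - composition.animal_fraction))
    from .domain import IAA_KEYS
    lysine = effective * composition.iaa_per_g_protein[
        :, IAA_KEYS.index("lys")]

    groups = composition.groups
    all_groups = list(ANIMAL_GROUPS) + list(PLANT_GROUPS)
    group_masks = {g: groups == g for g in all_groups}

    def shares(per_food: np.ndarray) -> dict[str, np.ndarray]:
        total = per_food.sum(axis=1)
        if np.any(total <= 0):
            raise DomainError("individual with zero intake of the nutrient")
        out = {g: per_food[:, m].sum(axis=1) / total * 100.0
               for g, m in group_masks.items()}
        out["animal"] = sum(out[g] for g in ANIMAL_GROUPS)
        out["plant"] = sum(out[g] for g in PLANT_GROUPS)
        return out

    prot_shares = shares(effective)
    lys_shares = shares(lysine)

    sex = np.array([ind_by_id[i].sex for i in ids])
    w = np.array([ind_by_id[i].survey_weight for i in ids])
    rows = []
    row_order = (["animal"] + list(ANIMAL_GROUPS)
                 + ["plant"] + list(PLANT_GROUPS))
    for g in row_order:
        row = {"group": g}
        for label, mask in (("men", sex == "male"), ("women", sex == "female")):
            if not mask.any():
                continue
            pm, ps = _weighted_mean_sd(prot_shares[g][mask], w[mask])
            lm, ls = _weighted_mean_sd(lys_shares[g][mask], w[mask])
            row[f"protein_{label}_mean"] = pm
            row[f"protein_{label}_sd"] = ps
            row[f"lysine_{label}_mean"] = lm
            row[f"lysine_{label}_sd"] = ls
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    """OLS association between an intake:EAR ratio and the plant-protein
    share of the diet (in percentage points)."""

    outcome: str
    slope_per_pct: float         # change in intake:EAR per +1 point share
    slope_per_10pct: float       # same, per +10 points
    intercept: float
    r_squared: float
    p_value: float
    conf_int: tuple[float, float]
    adjusted: bool
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise DomainError("R^2 outside [0, 1]")


def association_regression(usual: pd.DataFrame,
                           individuals: Sequence[Individual],
                           outcome: str,
                           adjusted: bool = False,
                           ears: EARTable = EARTable(),
                           ) -> RegressionResult:
    """Regress the usual intake:EAR ratio of ``outcome`` (``'protein'`` or
    an IAA key) on the plant-protein share, optionally adjusting for age,
    sex, BMI and non-alcohol energy intake."""
    if len(usual) < 10:
        raise DomainError("need >= 10 individuals for the regression")
    ind_by_id = {i.individual_id: i for i in individuals}
    ids = [i for i in usual.index]
    perkg = (usual["protein_g_perkg"] if outcome == "protein"
             else usual[f"iaa_{outcome}_mg_perkg"])
    y = (perkg / ears.ear(outcome)).to_numpy(dtype=float)
    share = (usual["plant_protein_g"]
             / (usual["plant_protein_g"] + usual["animal_protein_g"])
             ).to_numpy(dtype=float) * 100.0

    data = {"plant_share_pct": share}
    if adjusted:
        data["age_y"] = np.array([ind_by_id[i].age_y for i in ids])
        data["female"] = np.array(
            [1.0 if ind_by_id[i].sex == "female" else 0.0 for i in ids])
        data["bmi"] = np.array([ind_by_id[i].bmi for i in ids])
        data["energy_kcal_noalc"] = usual["energy_kcal_noalc"].to_numpy()
    X = sm.add_constant(pd.DataFrame(data))
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params["plant_share_pct"])
    ci = fit.conf_int().loc["plant_share_pct"]
    return RegressionResult(
        outcome=outcome,
        slope_per_pct=slope,
        slope_per_10pct=slope * 10.0,
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues["plant_share_pct"]),
        conf_int=(float(ci[0]), float(ci[1])),
        adjusted=adjusted,
        coefficients={k: float(v) for k, v in fit.params.items()},
    )


def regression_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    rows = [{
        "outcome": r.outcome, "adjusted": r.adjusted,
        "slope_per_pct": r.slope_per_pct,
        "slope_per_10pct": r.slope_per_10pct,
        "intercept": r.intercept, "r_squared": r.r_squared,
        "p_value": r.p_value,
        "ci_lower": r.conf_int[0], "ci_upper": r.conf_int[1],
    } for r in results]
    return pd.DataFrame(rows)
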