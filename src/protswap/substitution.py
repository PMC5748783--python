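"""Graded substitution of animal protein by plant protein.

Four substitution models act on each individual's mean daily food
pattern. A fraction ``s`` of the grams of every *substitutable* animal
food is removed (so the protein shares among an individual's animal foods
stay constant), and the removed quantity is compensated with plant foods:

* **Model P** (protein-adjusted): the removed *protein* is returned via
  the individual's own plant-protein pattern (each plant protein source
  scaled equally), conserving total crude protein exactly — at the cost
  of a growing energy intake, because plant protein sources carry more
  energy per gram of protein than animal ones.
* **Model A** (energy-adjusted): the removed *non-alcohol energy* is
  returned via the individual's own plant energy pattern, conserving
  non-alcohol energy exactly.
* **Model B**: the removed energy is returned through a fixed mix of
  legumes, nuts and seeds (LNS) estimated from the population's observed
  LNS intake.
* **Model C** (lambda in (0, 1)): a fraction lambda of the removed energy
  goes through the LNS mix and 1 - lambda through the Model-A pattern;
  lambda = 0 is Model A, lambda = 1 is Model B.

Substituted diets shift each individual's usual nutrient intakes by a
deterministic delta; inadequacy is then re-evaluated by the probability
approach, producing prevalence-versus-plant-share curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adequacy import inadequacy_probability, prevalence
from .domain import (
    IAA_KEYS,
    LNS_GROUPS,
    CompositionTable,
    DietRecord,
    DomainError,
    EARTable,
    Individual,
)
from .intake import (
    REQUIREMENT_NUTRIENTS,
    DigestibilityPolicy,
    mean_patterns,
    nutrient_arrays,
)

_DEFAULT_S_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 2))


@dataclass(frozen=True)
class ModelSpec:
    """Substitution model: kind P/A/B/C plus the LNS fraction lambda."""

    kind: str
    lns_fraction: float = 0.0
    s_grid: tuple[float, ...] = _DEFAULT_S_GRID
    policy: DigestibilityPolicy = DigestibilityPolicy()

    def __post_init__(self) -> None:
        if self.kind not in ("P", "A", "B", "C"):
            raise DomainError(f"unknown model kind {self.kind!r}")
        if not 0.0 <= self.lns_fraction <= 1.0:
            raise DomainError("lns_fraction must lie in [0, 1]")
        grid = tuple(self.s_grid)
        if list(grid) != sorted(grid):
            raise DomainError("s_grid must be sorted")
        if not grid or grid[0] != 0.0:
            raise DomainError("s_grid must contain 0")
        if grid[0] < 0.0 or grid[-1] > 1.0:
            raise DomainError("s_grid must lie within [0, 1]")

    @property
    def effective_lambda(self) -> float | None:
        """LNS fraction of the substituting energy; None for Model P."""
        if self.kind == "P":
            return None
        if self.kind == "A":
            return 0.0
        if self.kind == "B":
            return 1.0
        return self.lns_fraction

    @classmethod
    def model(cls, name: str, **kwargs) -> "ModelSpec":
        """Build a spec from names like ``"A"``, ``"B"``, ``"P"`` or
        ``"C_40"`` (40% LNS)."""
        name = name.strip()
        if name.upper().startswith("C") and "_" in name:
            pct = float(name.split("_", 1)[1])
            return cls(kind="C", lns_fraction=pct / 100.0, **kwargs)
        return cls(kind=name.upper(), **kwargs)


@dataclass(frozen=True)
class LnsMix:
    """Shares of the legumes/nuts/seeds substitution mix over LNS foods,
    on the stated basis (energy by default), summing to 1."""

    shares: Mapping[str, float]
    basis: str = "energy"

    def __post_init__(self) -> None:
        if not self.shares:
            raise DomainError("empty LNS mix")
        vals = np.array(list(self.shares.values()))
        if np.any(vals < 0):
            raise DomainError("LNS shares must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise DomainError("LNS shares must sum to 1")


def build_lns_mix(records: Sequence[DietRecord],
                  composition: CompositionTable,
                  basis: str = "energy") -> LnsMix:
    """LNS mix from the population's observed legumes/nuts/seeds intake.

    Shares are proportional to the population-total intake of each LNS
    food on the chosen basis (``"energy"``: non-alcohol kcal;
    ``"protein"``: grams of crude protein).
    """
    if basis not in ("energy", "protein"):
        raise DomainError(f"unknown LNS mix basis {basis!r}")
    lns_idx = [i for i, g in enumerate(composition.groups)
               if g in LNS_GROUPS]
    if not lns_idx:
        raise DomainError("composition table has no legumes/nuts_seeds "
                          "foods; supply a default mix explicitly")
    totals = np.zeros(len(composition))
    for r in records:
        totals += composition.pattern_vector(r.consumptions)
    density = (composition.energy_per_g if basis == "energy"
               else composition.protein_per_g)
    amounts = totals[lns_idx] * density[lns_idx]
    if amounts.sum() <= 0:
        raise DomainError(
            "no legumes/nuts/seeds consumption observed anywhere; "
            "supply a default LnsMix explicitly")
    shares = amounts / amounts.sum()
    return LnsMix(shares={composition.food_ids[i]: float(sh)
                          for i, sh in zip(lns_idx, shares)}, basis=basis)


# ---------------------------------------------------------------------------
# Core pattern transformation
# ---------------------------------------------------------------------------

def substitute_patterns(patterns: np.ndarray,
                        composition: CompositionTable,
                        model: ModelSpec, s: float,
                        lns_mix: LnsMix | None = None) -> np.ndarray:
    """Apply one substitution step to an (n, n_foods) grams matrix.

    Returns the modified matrix; the input is not mutated.
    """
    if not 0.0 <= s <= 1.0:
        raise DomainError("s must lie in [0, 1]")
    P = np.atleast_2d(np.asarray(patterns, dtype=float)).copy()
    if s == 0.0:
        return P
    lam = model.effective_lambda
    if lam is not None and lam > 0.0 and lns_mix is None:
        raise DomainError(f"model {model.kind} needs an LnsMix")

    subst = composition.substitutable
    q_protein = s * (P[:, subst] @ composition.protein_per_g[subst])
    q_energy = s * (P[:, subst] @ composition.energy_per_g[subst])
    P[:, subst] *= (1.0 - s)

    pure_plant = composition.animal_fraction == 0.0
    if model.kind == "P":
        sel = pure_plant & (composition.protein_per_g > 0)
        denom = P[:, sel] @ composition.protein_per_g[sel]
        _require_pattern(denom, q_protein, "plant protein (Model P)")
        scale = np.divide(q_protein, denom, out=np.zeros_like(denom),
                          where=denom > 0)
        P[:, sel] *= (1.0 + scale[:, None])
        return P

    # energy-adjusted models
    via_pattern = (1.0 - lam) * q_energy
    via_mix = lam * q_energy
    if np.any(via_pattern > 0):
        sel = pure_plant & (composition.energy_per_g > 0)
        denom = P[:, sel] @ composition.energy_per_g[sel]
        _require_pattern(denom, via_pattern, "plant energy (Model A part)")
        scale = np.divide(via_pattern, denom, out=np.zeros_like(denom),
                          where=denom > 0)
        P[:, sel] *= (1.0 + scale[:, None])
    if np.any(via_mix > 0):
        for food_id, share in lns_mix.shares.items():
            j = composition.index[food_id]
            if composition.energy_per_g[j] <= 0:
                raise DomainError(
                    f"LNS food {food_id!r} has zero energy density")
            P[:, j] += via_mix * share / composition.energy_per_g[j]
    return P


def _require_pattern(denom: np.ndarray, needed: np.ndarray,
                     what: str) -> None:
    bad = (denom <= 0) & (needed > 0)
    if np.any(bad):
        raise DomainError(
            f"{int(bad.sum())} individual(s) have no {what} pattern to "
            "scale; use a model with lns_fraction > 0 for them")


def substitute_individual(
    mean_daily_pattern: np.ndarray | Mapping[str, float],
    model: ModelSpec, s: float,
    lns_mix: LnsMix | None,
    composition: CompositionTable,
) -> tuple[np.ndarray, dict[str, float]]:
    """One individual's substituted pattern and its nutrient delta.

    The pattern may be a grams vector in composition order or a
    ``{food_id: grams}`` mapping. The delta maps nutrient columns to
    (substituted - baseline) daily amounts; entries can be negative, so it
    is a plain mapping rather than a (non-negative) nutrient vector.
    """
    if isinstance(mean_daily_pattern, Mapping):
        base = composition.pattern_vector(mean_daily_pattern.items())
    else:
        base = np.asarray(mean_daily_pattern, dtype=float)
    new = substitute_patterns(base[None, :], composition, model, s,
                              lns_mix)[0]
    before = nutrient_arrays(base, composition, model.policy)
    after = nutrient_arrays(new, composition, model.policy)
    delta = {key: float(after[key][0] - before[key][0])
             for key in before}
    return new, delta


# ---------------------------------------------------------------------------
# Population curves
# ---------------------------------------------------------------------------

@dataclass
class SimulationCurve:
    """Prevalence-versus-plant-share curve for one substitution model.

    ``table`` has one row per substitution step ``s`` with the weighted
    mean plant-protein share (percent of total protein), weighted mean
    daily non-alcohol energy, and per-nutrient prevalence of inadequacy
    with Wald 95% CI (columns ``prev_<nutrient>``, ``lo_<nutrient>``,
    ``hi_<nutrient>``).
    """

    model: ModelSpec
    table: pd.DataFrame

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()


def simulate_curve(
    individuals: Sequence[Individual],
    records: Sequence[DietRecord],
    usual: pd.DataFrame,
    model: ModelSpec,
    composition: CompositionTable,
    ears: EARTable = EARTable(),
    lns_mix: LnsMix | None = None,
) -> SimulationCurve:
    """Sweep the substitution grid and re-evaluate inadequacy.

    For every ``s`` each individual's mean daily pattern is substituted,
    the resulting deterministic nutrient delta is added to their usual
    intakes (within-person variance is unchanged by a deterministic
    shift), and the weighted prevalence of inadequacy is recomputed for
    protein and the nine IAA.
    """
    lam = model.effective_lambda
    if lam is not None and lam > 0.0 and lns_mix is None:
        lns_mix = build_lns_mix(records, composition)

    ids, base_patterns = mean_patterns(records, composition)
    ind_by_id = {i.individual_id: i for i in individuals}
    missing = [i for i in ids if i not in ind_by_id]
    if missing:
        raise DomainError(f"records for unknown individual(s): {missing}")
    weights = np.array([ind_by_id[i].survey_weight for i in ids])
    body_kg = np.array([ind_by_id[i].weight_kg for i in ids])
    usual = usual.loc[ids]

    base = nutrient_arrays(base_patterns, composition, model.policy)
    rows = []
    for s in model.s_grid:
        new_patterns = substitute_patterns(base_patterns, composition,
                                           model, float(s), lns_mix)
        new = nutrient_arrays(new_patterns, composition, model.policy)
        shifted = {
            col: np.maximum(
                usual[col].to_numpy() + (new[col] - base[col]), 0.0)
            for col in ("protein_g", "energy_kcal_noalc",
                        "plant_protein_g", "animal_protein_g")
            + tuple(f"iaa_{k}_mg" for k in IAA_KEYS)}
        with np.errstate(invalid="ignore"):
            share = np.divide(new["plant_protein_g"], new["protein_g"],
                              out=np.zeros_like(new["protein_g"]),
                              where=new["protein_g"] > 0)
        row = {
            "s": float(s),
            "plant_share_pct": float(np.average(share, weights=weights)
                                     * 100.0),
            "energy_kcal": float(np.average(shifted["energy_kcal_noalc"],
                                            weights=weights)),
        }
        for nutrient in REQUIREMENT_NUTRIENTS:
            col = ("protein_g" if nutrient == "protein"
                   else f"iaa_{nutrient}_mg")
            perkg = shifted[col] / body_kg
            probs = inadequacy_probability(perkg, ears.ear(nutrient),
                                           ears.cv)
            res = prevalence(probs, weights, nutrient=nutrient)
            row[f"prev_{nutrient}"] = res.prevalence_pct
            row[f"lo_{nutrient}"] = res.ci_lower_pct
            row[f"hi_{nutrient}"] = res.ci_upper_pct
        rows.append(row)
    return SimulationCurve(model=model, table=pd.DataFrame(rows))


def find_crossing(curve: SimulationCurve, nutrient: str,
                  level_pct: float) -> float | None:
    """Mean plant-protein share (percent) at which the prevalence of
    inadequacy for ``nutrient`` first crosses ``level_pct``.

    Linear interpolation between adjacent grid points on the (plant
    share, prevalence) curve; returns ``None`` when the level is never
    bracketed. A level hit exactly at a grid point returns that point's
    share.
    """
    x = curve.column("plant_share_pct")
    y = curve.column(f"prev_{nutrient}")
    for i in range(len(x)):
        if y[i] == level_pct:
            return float(x[i])
        if i + 1 < len(x) and (y[i] - level_pct) * (y[i + 1] - level_pct) < 0:
            frac = (level_pct - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    return None


def plot_curves(curves: Mapping[str, SimulationCurve],
                nutrients: Sequence[str] = ("protein", "lys"),
                path: str | None = None):
    """Prevalence-vs-plant-share chart with CI bands, one line style per
    model label and one colour per nutrient."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    styles = ["-", "--", ":", "-.", (0, (3, 1, 1, 1)), (0, (5, 2))]
    for (label, curve), style in zip(curves.items(), styles * 10):
        x = curve.column("plant_share_pct")
        for nutrient, color in zip(nutrients, colors):
            ax.plot(x, curve.column(f"prev_{nutrient}"), linestyle=style,
                    color=color, label=f"{label} {nutrient}")
            ax.fill_between(x, curve.column(f"lo_{nutrient}"),
                            curve.column(f"hi_{nutrient}"),
                            color=color, alpha=0.12)
    ax.set_xlabel("Mean plant protein share (% of total protein)")
    ax.set_ylabel("Prevalence of inadequacy (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
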