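"""Probability-approach nutrient inadequacy and survey-weighted prevalence.

An individual's requirement is modelled as Normal(EAR, cv * EAR); with a
usual intake y the probability of inadequacy is the probability that the
requirement exceeds y, i.e. Phi((EAR - y) / (cv * EAR)) with Phi the
standard normal left CDF. Population prevalence is the survey-weighted
mean of the individual probabilities, expressed in percent, with a Wald
binomial confidence interval computed on the unweighted sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .domain import DomainError, EARTable
from .intake import REQUIREMENT_NUTRIENTS


@dataclass(frozen=True)
class PrevalenceResult:
    """Weighted prevalence of inadequacy for one nutrient, in percent."""

    nutrient: str
    prevalence_pct: float
    ci_lower_pct: float
    ci_upper_pct: float
    n: int
    weighted: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower_pct <= self.prevalence_pct
                <= self.ci_upper_pct <= 100.0):
            raise DomainError(
                f"{self.nutrient}: inconsistent prevalence/CI ordering")


def inadequacy_probability(usual_perkg, ear: float, cv: float):
    """P(requirement > intake) for usual intake(s) ``usual_perkg``.

    Equals exactly 0.5 when intake equals the EAR, and decreases strictly
    and continuously in the intake. Accepts scalars or arrays.
    """
    if ear <= 0:
        raise DomainError("ear must be > 0")
    if not 0.0 < cv < 1.0:
        raise DomainError("cv must lie in (0, 1)")
    y = np.asarray(usual_perkg, dtype=float)
    if np.any(y < 0):
        raise DomainError("usual intake must be >= 0")
    p = stats.norm.cdf((ear - y) / (cv * ear))
    return float(p) if np.isscalar(usual_perkg) else p


def mc_oracle_probability(usual_perkg: float, ear: float, cv: float,
                          n_draws: int = 1_000_000,
                          seed: int = 0) -> float:
    """Monte-Carlo check of :func:`inadequacy_probability`: fraction of
    requirement draws ~ Normal(EAR, cv*EAR) exceeding the intake."""
    if n_draws < 100_000:
        raise DomainError("use at least 1e5 draws for a meaningful oracle")
    rng = np.random.default_rng(seed)
    req = rng.normal(ear, cv * ear, size=n_draws)
    return float(np.mean(req > usual_perkg))


def wald_ci(prevalence_pct: float, n: int, level: float = 0.95,
            ) -> tuple[float, float]:
    """Wald binomial interval p +- z * sqrt(p(100-p)/n) on the percent
    scale, clipped to [0, 100]."""
    if not 0.0 <= prevalence_pct <= 100.0:
        raise DomainError("prevalence_pct outside [0, 100]")
    if n < 1:
        raise DomainError("n must be >= 1")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(prevalence_pct * (100.0 - prevalence_pct) / n)
    return (float(max(0.0, prevalence_pct - half)),
            float(min(100.0, prevalence_pct + half)))


def prevalence(probabilities: Sequence[float],
               survey_weights: Sequence[float] | None = None,
               nutrient: str = "", level: float = 0.95) -> PrevalenceResult:
    """Survey-weighted mean of individual inadequacy probabilities, as a
    percentage, with a Wald CI on the unweighted n."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise DomainError("empty probability vector")
    if np.any((p < 0) | (p > 1)):
        raise DomainError("probabilities must lie in [0, 1]")
    if survey_weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(survey_weights, dtype=float)
        if w.shape != p.shape:
            raise DomainError("weights and probabilities differ in length")
        if np.any(w <= 0):
            raise DomainError("survey weights must be > 0")
    prev = float(np.average(p, weights=w) * 100.0)
    lo, hi = wald_ci(prev, p.size, level)
    return PrevalenceResult(nutrient=nutrient, prevalence_pct=prev,
                            ci_lower_pct=lo, ci_upper_pct=hi, n=p.size,
                            weighted=survey_weights is not None)


def population_inadequacy(usual_perkg: pd.DataFrame,
                          weights: Sequence[float],
                          ears: EARTable = EARTable(),
                          ) -> dict[str, PrevalenceResult]:
    """Prevalence of inadequacy for protein and each IAA.

    ``usual_perkg`` columns are the requirement nutrients (``protein`` in
    g/kg/d, IAA keys in mg/kg/d), one row per individual.
    """
    out = {}
    for nutrient in REQUIREMENT_NUTRIENTS:
        probs = inadequacy_probability(
            usual_perkg[nutrient].to_numpy(), ears.ear(nutrient), ears.cv)
        out[nutrient] = prevalence(probs, weights, nutrient=nutrient)
    return out


def prevalence_frame(results: dict[str, PrevalenceResult]) -> pd.DataFrame:
    """Flatten prevalence results for serialization."""
    rows = [{
        "nutrient": r.nutrient, "prevalence_pct": r.prevalence_pct,
        "ci_lower_pct": r.ci_lower_pct, "ci_upper_pct": r.ci_upper_pct,
        "n": r.n, "weighted": r.weighted,
    } for r in results.values()]
    return pd.DataFrame(rows)
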