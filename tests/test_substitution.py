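"""Substitution models: hand-arithmetic oracles, conservation laws and
curve behaviour."""

import numpy as np
import pandas as pd
import pytest

from protswap.domain import (
    CompositionTable,
    DietRecord,
    DomainError,
    EARTable,
    Individual,
)
from protswap.intake import (
    DigestibilityPolicy,
    mean_patterns,
    nutrient_arrays,
    usual_intakes,
)
from protswap.substitution import (
    LnsMix,
    ModelSpec,
    build_lns_mix,
    find_crossing,
    plot_curves,
    simulate_curve,
    substitute_individual,
    substitute_patterns,
)

from .conftest import make_food

TOY_PATTERN = {"beef": 200.0, "pasta": 400.0}


class TestModelSpec:
    def test_c40_parse(self):
        spec = ModelSpec.model("C_40")
        assert spec.kind == "C"
        assert spec.effective_lambda == pytest.approx(0.40)

    def test_effective_lambdas(self):
        assert ModelSpec.model("A").effective_lambda == 0.0
        assert ModelSpec.model("B").effective_lambda == 1.0
        assert ModelSpec.model("P").effective_lambda is None

    @pytest.mark.parametrize("grid", [
        (0.5, 0.2), (0.2, 0.5), (0.0, 1.5),
    ])
    def test_bad_grid_rejected(self, grid):
        with pytest.raises(DomainError):
            ModelSpec(kind="A", s_grid=grid)

    def test_lns_mix_must_sum_to_one(self):
        with pytest.raises(DomainError):
            LnsMix(shares={"lentils": 0.6, "almonds": 0.3})


class TestToyOracles:
    """200 g beef (20 g protein, 200 kcal /100 g) + 400 g pasta
    (5 g protein, 150 kcal /100 g): all numbers checkable by hand."""

    def test_s_zero_is_identity(self, toy_composition):
        new, delta = substitute_individual(TOY_PATTERN, ModelSpec.model("A"),
                                           0.0, None, toy_composition)
        np.testing.assert_allclose(
            new, toy_composition.pattern_vector(TOY_PATTERN.items()))
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in delta.values())

    def test_model_a_half_substitution(self, toy_composition):
        # remove 100 g beef (20 g protein, 200 kcal); return 200 kcal as
        # 133.33 g pasta carrying 6.667 g plant protein (pre-penalty)
        new, _ = substitute_individual(TOY_PATTERN, ModelSpec.model("A"),
                                       0.5, None, toy_composition)
        beef, pasta = new
        assert beef == pytest.approx(100.0)
        assert pasta == pytest.approx(400.0 + 400.0 / 3.0)
        crude_plant = pasta * 0.05
        crude_total = beef * 0.20 + crude_plant
        assert crude_plant / crude_total == pytest.approx(4.0 / 7.0)
        # raw plant share 57.1%
        assert crude_plant / crude_total * 100 == pytest.approx(57.14,
                                                                abs=0.01)

    def test_model_p_half_substitution(self, toy_composition):
        # return the removed 20 g protein as 400 g pasta; crude protein
        # conserved at 60 g
        new, delta = substitute_individual(TOY_PATTERN, ModelSpec.model("P"),
                                           0.5, None, toy_composition)
        beef, pasta = new
        assert beef == pytest.approx(100.0)
        assert pasta == pytest.approx(800.0)
        assert beef * 0.20 + pasta * 0.05 == pytest.approx(60.0)
        # energy inflates: +400 g pasta at 1.5 kcal/g - 100 g beef at 2
        assert delta["energy_kcal_noalc"] == pytest.approx(400.0)

    def test_full_substitution_empties_animal(self, toy_composition):
        new, _ = substitute_individual(TOY_PATTERN, ModelSpec.model("A"),
                                       1.0, None, toy_composition)
        assert new[0] == 0.0

    def test_no_plant_pattern_raises(self, toy_composition):
        with pytest.raises(DomainError, match="no plant"):
            substitute_individual({"beef": 200.0}, ModelSpec.model("A"),
                                  0.5, None, toy_composition)


class TestLnsMix:
    def test_single_lns_food(self):
        comp = CompositionTable([
            make_food("lentils", "legumes", 9.0, 120.0, af=0.0, lys=70.0),
            make_food("beef", "red_meat", 26.0, 170.0, af=1.0, lys=90.0)])
        recs = [DietRecord("A", 1, (("lentils", 50.0), ("beef", 100.0)))]
        mix = build_lns_mix(recs, comp)
        assert mix.shares == {"lentils": 1.0}

    def test_equal_energy_gives_half_half(self):
        comp = CompositionTable([
            make_food("lentils", "legumes", 9.0, 120.0, af=0.0),
            make_food("almonds", "nuts_seeds", 21.0, 600.0, af=0.0)])
        recs = [DietRecord("A", 1, (("lentils", 500.0), ("almonds", 100.0)))]
        mix = build_lns_mix(recs, comp)
        assert mix.shares["lentils"] == pytest.approx(0.5)
        assert mix.shares["almonds"] == pytest.approx(0.5)

    def test_no_lns_consumption_errors(self):
        comp = CompositionTable([
            make_food("lentils", "legumes", 9.0, 120.0, af=0.0),
            make_food("beef", "red_meat", 26.0, 170.0, af=1.0)])
        recs = [DietRecord("A", 1, (("beef", 100.0),))]
        with pytest.raises(DomainError, match="default"):
            build_lns_mix(recs, comp)

    def test_beef_replacement_protein_split(self, small_survey):
        """1 g of substituted beef protein maps to legume and nuts protein
        in roughly the observed 0.17 : 0.07 ratio."""
        _, comp, _, records = small_survey
        mix = build_lns_mix(records, comp)
        beef = comp["beef"]
        kcal = 1.0 / (beef.protein_g_per_100g / 100.0) \
            * beef.energy_kcal_per_100g / 100.0
        legume = nuts = 0.0
        for fid, share in mix.shares.items():
            food = comp[fid]
            grams = kcal * share / (food.energy_kcal_per_100g / 100.0)
            protein = grams * food.protein_g_per_100g / 100.0
            if food.group == "legumes":
                legume += protein
            else:
                nuts += protein
        assert legume / nuts == pytest.approx(0.17 / 0.07, rel=0.20)


class TestConservation:
    @pytest.mark.parametrize("kind", ["P", "A", "B", "C"])
    def test_toy_conservation_along_grid(self, toy_composition, kind):
        comp = CompositionTable([
            make_food("beef", "red_meat", 20.0, 200.0, af=1.0, lys=90.0),
            make_food("pasta", "cereals", 5.0, 150.0, af=0.0, lys=28.0),
            make_food("lentils", "legumes", 9.0, 120.0, af=0.0, lys=70.0),
        ])
        base = comp.pattern_vector(
            [("beef", 200.0), ("pasta", 400.0), ("lentils", 50.0)])
        mix = LnsMix(shares={"lentils": 1.0})
        model = ModelSpec(kind=kind, lns_fraction=0.5)
        crude0 = float(base @ comp.protein_per_g)
        energy0 = float(base @ comp.energy_per_g)
        for s in np.linspace(0, 1, 11):
            new = substitute_patterns(base, comp, model, float(s), mix)[0]
            if kind == "P":
                assert float(new @ comp.protein_per_g) == pytest.approx(
                    crude0, rel=1e-9)
            else:
                assert float(new @ comp.energy_per_g) == pytest.approx(
                    energy0, rel=1e-9)

    @pytest.mark.parametrize("kind,lam", [
        ("P", 0.0), ("A", 0.0), ("B", 1.0), ("C", 0.4)])
    def test_synthetic_population_conservation(self, kind, lam):
        from protswap.synthetic import (
            SurveyConfig, generate_composition, generate_population)
        cfg = SurveyConfig(n_individuals=200)
        comp = generate_composition(cfg)
        _, records = generate_population(cfg, comp, seed=3)
        _, patterns = mean_patterns(records, comp)
        mix = build_lns_mix(records, comp)
        model = ModelSpec(kind=kind, lns_fraction=lam)
        crude0 = patterns @ comp.protein_per_g
        energy0 = patterns @ comp.energy_per_g
        for s in np.linspace(0, 1, 6):
            new = substitute_patterns(patterns, comp, model, float(s), mix)
            if kind == "P":
                np.testing.assert_allclose(new @ comp.protein_per_g,
                                           crude0, rtol=1e-9)
            else:
                np.testing.assert_allclose(new @ comp.energy_per_g,
                                           energy0, rtol=1e-9)

    def test_animal_proportions_preserved(self):
        from protswap.synthetic import (
            SurveyConfig, generate_composition, generate_population)
        cfg = SurveyConfig(n_individuals=20)
        comp = generate_composition(cfg)
        _, records = generate_population(cfg, comp, seed=8)
        _, patterns = mean_patterns(records, comp)
        mix = build_lns_mix(records, comp)
        new = substitute_patterns(patterns, comp, ModelSpec.model("A"),
                                  0.6, mix)
        subst = comp.substitutable
        before = patterns[:, subst] * comp.protein_per_g[subst]
        after = new[:, subst] * comp.protein_per_g[subst]
        ratio_before = before / before.sum(axis=1, keepdims=True)
        ratio_after = after / after.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(ratio_after, ratio_before, rtol=1e-9)


@pytest.fixture(scope="module")
def toy_setup(toy_composition, toy_individual):
    records = [DietRecord("T1", d, (("beef", 200.0), ("pasta", 400.0)))
               for d in (1, 2)]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance toy records
        usual, _ = usual_intakes(records, [toy_individual], toy_composition)
    return toy_composition, [toy_individual], records, usual


class TestSimulateCurve:
    def test_s_zero_matches_baseline(self, toy_setup):
        comp, inds, recs, usual = toy_setup
        model = ModelSpec(kind="A", s_grid=(0.0,))
        curve = simulate_curve(inds, recs, usual, model, comp)
        row = curve.table.iloc[0]
        pen_plant = 20.0 * 0.95
        assert row["plant_share_pct"] == pytest.approx(
            pen_plant / (40.0 + pen_plant) * 100.0)

    def test_brute_force_equivalence(self, toy_setup):
        """Every grid point of the curve matches a from-scratch
        recomputation with plain arithmetic (no incremental shortcuts)."""
        from scipy.stats import norm
        comp, inds, recs, usual = toy_setup
        grid = tuple(np.round(np.linspace(0, 1, 5), 3))
        model = ModelSpec(kind="A", s_grid=grid)
        curve = simulate_curve(inds, recs, usual, model, comp)
        ears = EARTable()
        for i, s in enumerate(grid):
            beef = 200.0 * (1 - s)
            removed_kcal = 200.0 * s * 2.0
            pasta = 400.0 + removed_kcal / 1.5
            crude_plant = pasta * 0.05
            pen_plant = crude_plant * 0.95
            animal = beef * 0.20
            protein = animal + pen_plant
            # the toy records have zero within-person variance, so usual
            # intake equals the pattern intake and the shifted usual is
            # exactly the substituted pattern's intake
            perkg = protein / 70.0
            prob = norm.cdf((0.66 - perkg) / (0.125 * 0.66))
            row = curve.table.iloc[i]
            assert row["plant_share_pct"] == pytest.approx(
                pen_plant / protein * 100.0, rel=1e-9)
            assert row["prev_protein"] == pytest.approx(prob * 100.0,
                                                        rel=1e-9)
            lys = (animal * 90.0 + pen_plant * 28.0) / 70.0
            prob_lys = norm.cdf((30.0 - lys) / (0.125 * 30.0))
            assert row["prev_lys"] == pytest.approx(prob_lys * 100.0,
                                                    rel=1e-6, abs=1e-9)

    def test_monotone_protein_prevalence_model_a(self, small_survey,
                                                 small_usual):
        _, comp, inds, recs = small_survey
        usual, _ = small_usual
        grid = tuple(np.round(np.linspace(0, 1, 11), 2))
        curve = simulate_curve(inds, recs, usual,
                               ModelSpec(kind="A", s_grid=grid), comp)
        prev = curve.column("prev_protein")
        assert np.all(np.diff(prev) >= -1e-9)
        share = curve.column("plant_share_pct")
        assert np.all(np.diff(share) >= -1e-9)

    def test_lambda_ordering_at_fixed_s(self, small_survey, small_usual):
        _, comp, inds, recs = small_survey
        usual, _ = small_usual
        mix = build_lns_mix(recs, comp)
        grid = (0.0, 0.6)
        prevs = []
        for lam in (0.0, 0.2, 0.5, 0.8, 1.0):
            curve = simulate_curve(
                inds, recs, usual,
                ModelSpec(kind="C", lns_fraction=lam, s_grid=grid),
                comp, lns_mix=mix)
            prevs.append(curve.table["prev_protein"].iloc[-1])
        assert all(b <= a + 1e-9 for a, b in zip(prevs, prevs[1:]))

    def test_model_p_energy_increases(self, small_survey, small_usual):
        _, comp, inds, recs = small_survey
        usual, _ = small_usual
        curve = simulate_curve(inds, recs, usual,
                               ModelSpec(kind="P", s_grid=(0.0, 0.5, 1.0)),
                               comp)
        energy = curve.column("energy_kcal")
        assert energy[-1] > energy[0]


class TestFindCrossing:
    def _curve(self, shares, prevs):
        table = pd.DataFrame({
            "s": np.linspace(0, 1, len(shares)),
            "plant_share_pct": shares,
            "prev_protein": prevs})
        return type("C", (), {
            "column": lambda self, name, t=table: t[name].to_numpy()})()

    def test_linear_interpolation_by_hand(self):
        c = self._curve([40.0, 60.0], [2.0, 8.0])
        assert find_crossing(c, "protein", 5.0) == pytest.approx(50.0)

    def test_level_below_curve_absent(self):
        c = self._curve([40.0, 60.0], [2.0, 8.0])
        assert find_crossing(c, "protein", 1.0) is None

    def test_exact_grid_point(self):
        c = self._curve([40.0, 50.0, 60.0], [2.0, 5.0, 8.0])
        assert find_crossing(c, "protein", 5.0) == pytest.approx(50.0)


def test_plot_curves_writes_file(tmp_path, small_survey, small_usual):
    _, comp, inds, recs = small_survey
    usual, _ = small_usual
    curve = simulate_curve(inds, recs, usual,
                           ModelSpec(kind="A", s_grid=(0.0, 0.5, 1.0)),
                           comp)
    out = tmp_path / "figure.png"
    plot_curves({"A": curve}, path=str(out))
    assert out.exists() and out.stat().st_size > 0
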