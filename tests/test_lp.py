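"""Least-cost LP: requirement scaling, matrix assembly, solving, verification."""

import numpy as np
import pytest

from rutfopt import (
    ConstraintSpec,
    Formulation,
    Ingredient,
    NutrientProfile,
    RequirementSet,
    build_lp,
    constraint_violations,
    formulate_series,
    load_constraint_spec,
    requirement_to_density,
    solve_lp,
    study_constraints,
    validate_formulation,
)
from rutfopt.errors import DataValidationError, MissingPriceError, SchemaError
from rutfopt.model import PriceTable


def ing(name, protein=10.0, fat=5.0):
    carb = 100.0 - protein - fat - 5.0
    return Ingredient(name, NutrientProfile(
        protein_pct=protein, fat_pct=fat, ash_pct=2.0, fiber_pct=3.0,
        carbohydrate_pct=carb, energy_kcal=4 * protein + 9 * fat + 4 * carb,
        basis="dry"))


class TestRequirementToDensity:
    def test_protein_minimum_at_energy_floor(self, requirements):
        minima = requirement_to_density(requirements, 452.0)
        assert minima["protein"] == pytest.approx(64 * 452 / 2615.2, abs=1e-6)
        assert minima["protein"] == pytest.approx(11.06, abs=0.005)
        assert minima["energy"] == 452.0

    def test_unit_scale_factor(self, requirements):
        # product whose 100 g supplies the whole day's energy: minima = daily amounts
        minima = requirement_to_density(requirements, requirements.energy_kcal_day)
        assert minima["protein"] == pytest.approx(64.0)
        assert minima["lys"] == pytest.approx(3.26)

    def test_per_protein_mode_uses_scoring_ratio(self, requirements):
        minima = requirement_to_density(requirements, 452.0, mode="per_protein")
        assert minima["lys"] == pytest.approx(
            3.26 / 64.0 * minima["protein"], rel=1e-12)

    def test_zero_reference_density_rejected(self, requirements):
        with pytest.raises(DataValidationError):
            requirement_to_density(requirements, 0.0)


class TestBuildLP:
    def test_structural_counts_without_nutrient_bounds(self):
        p = build_lp([ing("x"), ing("y")], {"x": 1.0, "y": 2.0}, ConstraintSpec())
        assert p.n_equalities == 1
        assert p.n_inequalities == 0
        assert len(p.bounds) == 2

    def test_study_restrictions_present(self, ingset, price_table, requirements):
        spec = study_constraints(requirements, ("rice", 7.0))
        priced = {n: ingset[n] for n in price_table.ingredients}
        p = build_lp(priced, price_table.for_year(2004), spec)
        assert "fat:max" in p.row_labels and "energy:min" in p.row_labels
        fat_row = p.row_labels.index("fat:max")
        assert p.b_ub[fat_row] == 20.0
        energy_row = p.row_labels.index("energy:min")
        assert p.b_ub[energy_row] == -452.0
        sugar = p.names.index("sugar")
        assert p.bounds[sugar] == (0.0, 14.0)
        rice = p.names.index("rice")
        assert p.bounds[rice] == (7.0, 7.0)

    def test_missing_price_names_ingredient(self):
        with pytest.raises(MissingPriceError, match="y"):
            build_lp([ing("x"), ing("y")], {"x": 1.0}, ConstraintSpec())

    def test_constrained_nutrient_must_exist(self):
        spec = ConstraintSpec(nutrient_bounds={"lys": (0.5, None)})
        with pytest.raises(SchemaError, match="lys"):
            build_lp([ing("x"), ing("y")], {"x": 1.0, "y": 1.0}, spec)


class TestSolveLP:
    def test_dominance_picks_cheapest(self):
        p = build_lp([ing("x"), ing("y")], {"x": 1.0, "y": 2.0}, ConstraintSpec())
        s = solve_lp(p)
        assert s.status == "optimal"
        assert s.formulation.components["x"] == pytest.approx(100.0)
        assert s.cost_usd_per_kg == pytest.approx(1.0)

    def test_impossible_protein_floor_is_infeasible(self):
        spec = ConstraintSpec(nutrient_bounds={"protein": (50.0, None)})
        s = solve_lp(build_lp([ing("x", protein=10), ing("y", protein=20)],
                              {"x": 1.0, "y": 2.0}, spec))
        assert s.status == "infeasible"
        assert s.formulation is None

    def test_single_ingredient_degenerate(self):
        s = solve_lp(build_lp([ing("x")], {"x": 0.5}, ConstraintSpec()))
        assert s.status == "optimal"
        assert s.formulation.components == {"x": 100.0}
        infeasible = solve_lp(build_lp(
            [ing("x", protein=10)], {"x": 0.5},
            ConstraintSpec(nutrient_bounds={"protein": (20.0, None)})))
        assert infeasible.status == "infeasible"

    def test_solution_feasible_and_cost_consistent(self, ingset, price_table,
                                                   requirements):
        spec = study_constraints(requirements, ("rice", 7.0))
        priced = {n: ingset[n] for n in price_table.ingredients}
        prices = price_table.for_year(2004)
        s = solve_lp(build_lp(priced, prices, spec))
        assert s.status == "optimal"
        validate_formulation(s.formulation)
        assert constraint_violations(s.formulation, priced, spec, tol=1e-6) == []
        recomputed = sum(pct / 100 * prices[n]
                         for n, pct in s.formulation.components.items())
        assert s.cost_usd_per_kg == pytest.approx(recomputed, rel=1e-12)

    def test_price_scaling_invariance(self, ingset, price_table, requirements):
        # doubling every price must double the cost and keep the blend identical
        spec = study_constraints(requirements, ("barley", 5.0))
        priced = {n: ingset[n] for n in price_table.ingredients}
        prices = price_table.for_year(2006)
        s1 = solve_lp(build_lp(priced, prices, spec))
        s2 = solve_lp(build_lp(priced, {k: 2.0 * v for k, v in prices.items()}, spec))
        assert s1.status == s2.status == "optimal"
        assert s2.cost_usd_per_kg == 2.0 * s1.cost_usd_per_kg
        for n in priced:
            assert s2.formulation.components[n] == pytest.approx(
                s1.formulation.components[n], abs=1e-7)

    def test_binding_constraints_have_zero_slack(self, ingset, price_table,
                                                 requirements):
        spec = study_constraints(requirements, ("rice", 14.0))
        priced = {n: ingset[n] for n in price_table.ingredients}
        s = solve_lp(build_lp(priced, price_table.for_year(2005), spec))
        assert s.status == "optimal"
        assert "rice:min" in s.binding_constraints or "rice:max" in s.binding_constraints


class TestCandidateAudit:
    def test_published_recipes_meet_sugar_koji_fat_limits(self, formulations, ingset,
                                                          requirements):
        koji = {"A": ("rice", 7.0), "B": ("rice", 14.0), "C": ("rice", 21.0),
                "D": ("barley", 5.0), "E": ("barley", 10.0), "F": ("barley", 15.0)}
        for f in formulations:
            spec = study_constraints(requirements, koji[f.name])
            audit = ConstraintSpec(
                nutrient_bounds={"fat": spec.nutrient_bounds["fat"]},
                ingredient_bounds=spec.ingredient_bounds)
            assert constraint_violations(f, ingset, audit, tol=1e-6) == []

    def test_predicted_energy_sits_below_the_floor(self, formulations, ingset):
        # the published instance is *not* feasible for its own energy floor:
        # blended predicted energies are ~441 kcal/100 g against a 452 minimum
        from rutfopt import blend_profile
        for f in formulations:
            assert blend_profile(f, ingset).energy_kcal < 452.0


class TestSeries:
    def test_single_year_matches_direct_solve(self, ingset, price_table,
                                              requirements):
        spec = study_constraints(requirements, ("rice", 7.0))
        priced = {n: ingset[n] for n in price_table.ingredients}
        series = formulate_series(priced, price_table, spec, [2004])
        direct = solve_lp(build_lp(priced, price_table.for_year(2004), spec))
        assert series[2004].cost_usd_per_kg == pytest.approx(direct.cost_usd_per_kg)

    def test_identical_prices_give_identical_solutions(self, ingset, requirements):
        entries = {}
        for n in ingset:
            entries[(n, 2004)] = 0.5
            entries[(n, 2005)] = 0.5
        table = PriceTable(entries)
        spec = study_constraints(requirements, ("rice", 7.0))
        series = formulate_series(ingset, table, spec, [2004, 2005])
        assert series[2004].cost_usd_per_kg == series[2005].cost_usd_per_kg
        assert series[2004].formulation.components == \
            series[2005].formulation.components

    def test_missing_year_tagged(self, ingset, price_table, requirements):
        spec = study_constraints(requirements, ("rice", 7.0))
        priced = {n: ingset[n] for n in price_table.ingredients}
        with pytest.raises(MissingPriceError, match="2042"):
            formulate_series(priced, price_table, spec, [2042])


def test_constraint_spec_yaml_round_trip(tmp_path):
    import yaml

    spec = ConstraintSpec(nutrient_bounds={"fat": (None, 20.0), "energy": (452.0, None)},
                          ingredient_bounds={"sugar": (0.0, 14.0)})
    path = tmp_path / "spec.yaml"
    path.write_text(yaml.safe_dump(spec.to_dict()))
    back = load_constraint_spec(path)
    assert back.nutrient_bounds == spec.nutrient_bounds
    assert back.ingredient_bounds == spec.ingredient_bounds


def test_min_above_max_rejected():
    with pytest.raises(DataValidationError):
        ConstraintSpec(nutrient_bounds={"fat": (25.0, 20.0)})
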