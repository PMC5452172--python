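"""Scenario-transform oracles: linearity, conservation and equivalence."""

import dataclasses

import pytest

from dietsim import (
    AggregateTable,
    FoodItem,
    IntakeLine,
    NutrientProfile,
    Person,
    PopulationDataset,
    ReformulationParams,
    ScenarioSpec,
    compensate_energy,
    compute_replacement_ratio,
    moderate,
    population_mean_intake,
    reformulate,
    run_scenario,
    run_sensitivity_suite,
    substitute,
)
from dietsim.nutrients import MICRONUTRIENT_UNITS
from dietsim.scenarios import ScenarioError
from dietsim.synthetic import GeneratorConfig, default_archetypes, generate

ALL_CLASSES = ("core_food", "core_beverage", "discretionary_food",
               "discretionary_beverage")
DISC = ("discretionary_food", "discretionary_beverage")


def table_from_dataset(dataset) -> AggregateTable:
    """Aggregate columns of a person-level dataset (sports kept in the
    beverage column so the columns stay additive)."""
    table = AggregateTable()
    for column, classes in [
        ("total", ALL_CLASSES),
        ("core", ("core_food", "core_beverage")),
        ("discretionary", DISC),
        ("discretionary_foods", ("discretionary_food",)),
        ("discretionary_beverages", ("discretionary_beverage",)),
    ]:
        table[column] = population_mean_intake(dataset, classes).profile
    return table


# ---------------------------------------------------------------------------
# Moderation
# ---------------------------------------------------------------------------

class TestModeration:
    @pytest.mark.parametrize("target,classes", [
        ("foods", ("discretionary_food",)),
        ("beverages", ("discretionary_beverage",)),
        ("all", DISC),
    ])
    @pytest.mark.parametrize("fraction", [0.25, 0.5, 1.0])
    def test_linearity_oracle(self, synthetic_dataset, target, classes,
                              fraction):
        # with no compensation: modelled = base - fraction * class share,
        # exactly, nutrient by nutrient
        dataset, _ = synthetic_dataset
        spec = ScenarioSpec("moderation", target, fraction, 0.0)
        modelled = population_mean_intake(moderate(dataset, spec)).profile
        base = population_mean_intake(dataset).profile
        share = population_mean_intake(dataset, classes).profile
        for name, value in base.items():
            assert modelled.get(name) == pytest.approx(
                value - fraction * share.get(name), rel=1e-9, abs=1e-9
            )

    def test_fraction_zero_is_identity(self, tiny_dataset):
        spec = ScenarioSpec("moderation", "all", 0.0)
        out = moderate(tiny_dataset, spec)
        assert [l.grams for l in out.intakes] == [
            l.grams for l in tiny_dataset.intakes
        ]

    def test_composition_law(self, tiny_dataset):
        # applying twice with fraction f equals once with 1-(1-f)^2
        f = 0.3
        twice = moderate(
            moderate(tiny_dataset, ScenarioSpec("moderation", "all", f)),
            ScenarioSpec("moderation", "all", f),
        )
        once = moderate(
            tiny_dataset,
            ScenarioSpec("moderation", "all", 1 - (1 - f) ** 2),
        )
        a = population_mean_intake(twice).profile
        b = population_mean_intake(once).profile
        for name, value in a.items():
            assert b.get(name) == pytest.approx(value, rel=1e-12, abs=1e-12)

    def test_aggregate_equals_person_mode(self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        table = table_from_dataset(dataset)
        for target in ("foods", "beverages", "all"):
            spec = ScenarioSpec("moderation", target, 0.5)
            person = population_mean_intake(moderate(dataset, spec)).profile
            agg = moderate(table, spec)["total"]
            for name, value in person.items():
                assert agg.get(name) == pytest.approx(value, rel=1e-9,
                                                      abs=1e-9)


class TestCompensation:
    def _two_food_pool(self):
        foods = {
            "A": FoodItem("A", "a", "111", False, False,
                          composition=NutrientProfile(grams_food_weight=100.0,
                                                      energy=600.0,
                                                      sodium=100.0)),
            "B": FoodItem("B", "b", "121", False, False,
                          composition=NutrientProfile(grams_food_weight=100.0,
                                                      energy=400.0,
                                                      protein=10.0)),
        }
        persons = {"P": Person("P", 1.0)}
        intakes = [IntakeLine("P", "A", 100.0), IntakeLine("P", "B", 100.0)]
        return PopulationDataset(foods, persons, intakes)

    def test_hand_pro_rata(self):
        # 600/400 kJ pool, 100 kJ deficit, full compensation -> +60/+40 kJ
        ds = self._two_food_pool()
        out = compensate_energy(ds, deficit_kj=100.0, fraction=1.0)
        grams = {l.food_code: l.grams for l in out.intakes}
        assert grams["A"] * 6.0 - 600.0 == pytest.approx(60.0)
        assert grams["B"] * 4.0 - 400.0 == pytest.approx(40.0)

    def test_fraction_zero_no_change(self):
        ds = self._two_food_pool()
        out = compensate_energy(ds, deficit_kj=100.0, fraction=0.0)
        assert [l.grams for l in out.intakes] == [l.grams for l in ds.intakes]

    def test_empty_pool_raises(self):
        ds = self._two_food_pool()
        with pytest.raises(ScenarioError):
            compensate_energy(ds, 100.0, pool=frozenset({"core_beverage"}),
                              fraction=0.5)

    @pytest.mark.parametrize("fraction", [0.25, 0.75])
    def test_energy_conservation(self, synthetic_dataset, fraction):
        # energy added back == fraction x food-derived deficit
        dataset, _ = synthetic_dataset
        base = population_mean_intake(dataset).profile
        food_share = population_mean_intake(
            dataset, ["discretionary_food"]
        ).profile
        uncomp = population_mean_intake(
            moderate(dataset, ScenarioSpec("moderation", "all", 0.5))
        ).profile
        comp = population_mean_intake(
            moderate(dataset, ScenarioSpec("moderation", "all", 0.5, fraction))
        ).profile
        deficit = 0.5 * food_share.energy
        assert comp.energy - uncomp.energy == pytest.approx(
            fraction * deficit, rel=1e-9
        )
        assert comp.energy == pytest.approx(
            base.energy - 0.5 * population_mean_intake(dataset, DISC).profile.energy
            + fraction * deficit,
            rel=1e-9,
        )

    def test_beverage_deficit_never_compensated(self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        uncomp = population_mean_intake(
            moderate(dataset, ScenarioSpec("moderation", "beverages", 0.5))
        ).profile
        comp = population_mean_intake(
            moderate(dataset, ScenarioSpec("moderation", "beverages", 0.5, 0.75))
        ).profile
        assert comp.energy == pytest.approx(uncomp.energy, rel=1e-12)

    def test_compensation_adds_only_pool_nutrients(self, synthetic_dataset):
        # alcohol lives in beverages, outside the food pool: -50% always
        dataset, _ = synthetic_dataset
        base = population_mean_intake(dataset).profile
        for fraction in (0.0, 0.25, 0.75):
            spec = ScenarioSpec("moderation", "all", 0.5, fraction)
            modelled = population_mean_intake(moderate(dataset, spec)).profile
            assert modelled.alcohol / base.alcohol == pytest.approx(0.5,
                                                                    rel=1e-9)


# ---------------------------------------------------------------------------
# Substitution
# ---------------------------------------------------------------------------

class TestSubstitution:
    def test_mass_ledger_flat_ratio(self, synthetic_dataset):
        # grams added = ratio x grams removed; ratio 1 conserves total mass
        dataset, _ = synthetic_dataset
        base = population_mean_intake(dataset).profile
        spec = ScenarioSpec("substitution", "all", 0.5, replacement_ratios=1.0)
        modelled = population_mean_intake(substitute(dataset, spec)).profile
        assert modelled.grams_food_weight == pytest.approx(
            base.grams_food_weight, rel=1e-9
        )
        spec129 = ScenarioSpec("substitution", "all", 0.5,
                               replacement_ratios=1.29)
        m129 = population_mean_intake(substitute(dataset, spec129)).profile
        removed = 0.5 * population_mean_intake(dataset, DISC).profile.grams_food_weight
        assert m129.grams_food_weight - base.grams_food_weight == pytest.approx(
            (1.29 - 1.0) * removed, rel=1e-9
        )

    def test_100g_removed_adds_129g(self):
        foods = {
            "D": FoodItem("D", "d", "411", True, False,
                          composition=NutrientProfile(grams_food_weight=100.0,
                                                      energy=1000.0)),
            "C": FoodItem("C", "c", "241", False, False,
                          composition=NutrientProfile(grams_food_weight=100.0,
                                                      energy=200.0)),
        }
        persons = {"P": Person("P", 1.0)}
        ds = PopulationDataset(
            foods, persons,
            [IntakeLine("P", "D", 200.0), IntakeLine("P", "C", 50.0)],
        )
        out = substitute(ds, ScenarioSpec("substitution", "foods", 0.5,
                                          replacement_ratios=1.29))
        grams = {l.food_code: l.grams for l in out.intakes}
        assert grams["D"] == pytest.approx(100.0)
        assert grams["C"] == pytest.approx(50.0 + 129.0)

    def test_no_negative_grams_and_fraction_zero(self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        out = substitute(dataset,
                         ScenarioSpec("substitution", "all", 0.0))
        assert [l.grams for l in out.intakes[:len(dataset.intakes)]] == [
            l.grams for l in dataset.intakes
        ]
        out = substitute(dataset, ScenarioSpec("substitution", "all", 1.0))
        assert all(l.grams >= 0 for l in out.intakes)

    def test_missing_subgroup_ratio_raises(self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        spec = ScenarioSpec("substitution", "all", 0.5,
                            replacement_ratios={"411": 1.2})
        with pytest.raises(ScenarioError, match="subgroup"):
            substitute(dataset, spec)

    def test_fruit_veg_pool_receives_all_food_replacement(self,
                                                          synthetic_dataset):
        dataset, _ = synthetic_dataset
        spec = ScenarioSpec("substitution", "foods", 0.5,
                            substitution_pool="fruit_veg_only",
                            replacement_ratios=1.0)
        out = substitute(dataset, spec)
        pool_subgroups = spec.food_pool_subgroups

        def grams_by_food(ds):
            totals = {}
            for line in ds.intakes:
                w = ds.persons[line.person_id].weight
                totals[line.food_code] = totals.get(line.food_code, 0.0) \
                    + w * line.grams
            return totals

        base_totals = grams_by_food(dataset)
        out_totals = grams_by_food(out)
        for code, base_grams in base_totals.items():
            item = dataset.foods[code]
            delta = out_totals[code] - base_grams
            if item.is_discretionary and not item.is_beverage:
                assert delta < 0  # halved
            elif item.subgroup_code in pool_subgroups:
                assert delta > 0  # receives all food replacement
            elif not item.is_discretionary and not (
                item.is_beverage and not item.is_milk
            ):
                # core foods outside the fruit/veg pool stay untouched
                assert delta == pytest.approx(0.0, abs=1e-9)
        # ratio 1, foods only: total mass conserved
        base = population_mean_intake(dataset).profile
        modelled = population_mean_intake(out).profile
        assert modelled.grams_food_weight == pytest.approx(
            base.grams_food_weight, rel=1e-9
        )

    def test_empty_pool_raises(self):
        foods = {
            "D": FoodItem("D", "d", "411", True, False,
                          composition=NutrientProfile(grams_food_weight=100.0)),
        }
        ds = PopulationDataset(foods, {"P": Person("P", 1.0)},
                               [IntakeLine("P", "D", 100.0)])
        with pytest.raises(ScenarioError, match="pool"):
            substitute(ds, ScenarioSpec("substitution", "foods", 0.5))


class TestReplacementRatio:
    def test_identical_distributions_give_unity(self):
        foods = {
            "D": FoodItem("D", "d", "411", True, False,
                          composition=NutrientProfile(grams_food_weight=100.0)),
            "C": FoodItem("C", "c", "241", False, False,
                          composition=NutrientProfile(grams_food_weight=100.0)),
        }
        persons = {f"P{i}": Person(f"P{i}", 1.0) for i in range(5)}
        intakes = []
        for i, g in enumerate([50.0, 100.0, 150.0, 200.0, 250.0]):
            intakes.append(IntakeLine(f"P{i}", "D", g))
            intakes.append(IntakeLine(f"P{i}", "C", g))
        ds = PopulationDataset(foods, persons, intakes)
        assert compute_replacement_ratio(ds) == pytest.approx(1.0)

    def test_direct_median_quotient(self):
        # median source line 200 g, median target line 258 g -> 1.29
        foods = {
            "D": FoodItem("D", "d", "411", True, False,
                          composition=NutrientProfile(grams_food_weight=100.0)),
            "C": FoodItem("C", "c", "241", False, False,
                          composition=NutrientProfile(grams_food_weight=100.0)),
        }
        persons = {f"P{i}": Person(f"P{i}", 1.0) for i in range(3)}
        intakes = [
            IntakeLine("P0", "D", 100.0), IntakeLine("P1", "D", 200.0),
            IntakeLine("P2", "D", 300.0),
            IntakeLine("P0", "C", 129.0), IntakeLine("P1", "C", 258.0),
            IntakeLine("P2", "C", 387.0),
        ]
        ds = PopulationDataset(foods, persons, intakes)
        assert compute_replacement_ratio(ds) == pytest.approx(1.29)
        assert compute_replacement_ratio(
            ds, orientation="source_over_target"
        ) == pytest.approx(1 / 1.29)

    def test_empty_group_raises(self, tiny_dataset):
        with pytest.raises(ScenarioError):
            compute_replacement_ratio(
                tiny_dataset,
                source_labels=frozenset({"discretionary_beverage"}),
            )


# ---------------------------------------------------------------------------
# Reformulation
# ---------------------------------------------------------------------------

class TestReformulation:
    def test_conservation_laws(self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        base = population_mean_intake(dataset).profile
        spec = ScenarioSpec("reformulation", "all")
        modelled = population_mean_intake(reformulate(dataset, spec)).profile
        # total fat, protein, fiber and micronutrients invariant
        assert modelled.total_fat == pytest.approx(base.total_fat, rel=1e-9)
        assert modelled.protein == pytest.approx(base.protein, rel=1e-9)
        assert modelled.fiber == pytest.approx(base.fiber, rel=1e-9)
        for name in MICRONUTRIENT_UNITS:
            assert modelled.get(name) == pytest.approx(base.get(name),
                                                       rel=1e-9, abs=1e-12)
        # energy drop equals the removed sugar + alcohol energy
        d_sugar = base.added_sugars - modelled.added_sugars
        d_alc = base.alcohol - modelled.alcohol
        assert base.energy - modelled.energy == pytest.approx(
            16.736 * d_sugar + 29.288 * d_alc, rel=1e-9
        )
        # mass drop equals removed sugar + alcohol + sodium mass
        d_na = base.sodium - modelled.sodium
        assert base.grams_food_weight - modelled.grams_food_weight == \
            pytest.approx(d_sugar + d_alc + d_na / 1000.0, rel=1e-9)

    def test_zero_parameters_are_identity(self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        spec = ScenarioSpec(
            "reformulation", "all",
            reformulation=ReformulationParams(0.0, 0.0, 0.0, 0.0),
        )
        base = population_mean_intake(dataset).profile
        modelled = population_mean_intake(reformulate(dataset, spec)).profile
        for name, value in base.items():
            assert modelled.get(name) == pytest.approx(value, rel=1e-12,
                                                       abs=1e-12)

    def test_sweetener_energy_replacement_preserves_sugar_energy_and_mass(
            self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        base = population_mean_intake(dataset).profile
        spec = ScenarioSpec(
            "reformulation", "foods",
            reformulation=ReformulationParams(0.0, 0.25, 0.0, 0.0,
                                              sweetener_energy_replacement=True),
        )
        modelled = population_mean_intake(reformulate(dataset, spec)).profile
        assert modelled.energy == pytest.approx(base.energy, rel=1e-9)
        assert modelled.grams_food_weight == pytest.approx(
            base.grams_food_weight, rel=1e-9
        )
        assert modelled.added_sugars < base.added_sugars

    def test_sfa_swap_preserves_unsaturated_split_orientation(self):
        item = FoodItem(
            "D", "d", "411", True, False,
            composition=NutrientProfile(
                grams_food_weight=100.0, total_fat=10.0, sfa=6.0, mufa=3.0,
                pufa=1.0, energy=376.56,
            ),
        )
        ds = PopulationDataset({"D": item}, {"P": Person("P", 1.0)},
                               [IntakeLine("P", "D", 100.0)])
        out = reformulate(ds, ScenarioSpec("reformulation", "foods"))
        agg = population_mean_intake(out).profile
        assert agg.sfa == pytest.approx(3.0)
        assert agg.total_fat == pytest.approx(10.0)
        # removed 3 g SFA split 3:1 across MUFA:PUFA
        assert agg.mufa == pytest.approx(3.0 + 2.25)
        assert agg.pufa == pytest.approx(1.0 + 0.75)

    def test_aggregate_equals_person_mode(self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        table = table_from_dataset(dataset)
        for target in ("foods", "beverages", "all"):
            spec = ScenarioSpec("reformulation", target)
            person = population_mean_intake(reformulate(dataset, spec)).profile
            agg = reformulate(table, spec)["total"]
            for name, value in person.items():
                if name in ("mufa", "pufa"):
                    continue  # split uses item-level vs column-level ratios
                assert agg.get(name) == pytest.approx(value, rel=1e-9,
                                                      abs=1e-9)
            assert agg.mufa + agg.pufa == pytest.approx(
                person.mufa + person.pufa, rel=1e-9
            )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class TestRunScenario:
    def test_identity_spec_gives_zero_changes(self, synthetic_dataset):
        dataset, _ = synthetic_dataset
        res = run_scenario(dataset, ScenarioSpec("moderation", "all", 0.0))
        for name, pct in res.pct_change.items():
            if pct is not None:
                assert pct == pytest.approx(0.0, abs=1e-9)

    def test_reformulation_suite_sfa_envelope_aggregate(self, table1):
        # lower/primary/upper SFA bounds derived from the per-capita columns:
        # -r * 11.6 / 27.7 for r in (0.25, 0.50, 0.75)
        results = run_sensitivity_suite(table1, "reformulation")
        expected = {
            "lower": -0.25 * 11.6 / 27.7 * 100,
            "primary": -0.50 * 11.6 / 27.7 * 100,
            "upper": -0.75 * 11.6 / 27.7 * 100,
        }
        for key, value in expected.items():
            assert results[key].pct_change["sfa"] == pytest.approx(value,
                                                                   abs=1e-9)

    def test_moderation_suite_alcohol_always_halved(self, table1):
        results = run_sensitivity_suite(table1, "moderation")
        for res in results.values():
            assert res.pct_change["alcohol"] == pytest.approx(-50.0, abs=1e-9)

    def test_suite_on_discretionary_free_population_is_inert(self):
        archetypes = [
            a for a in default_archetypes() if not a.is_discretionary
        ]
        dataset, _ = generate(
            GeneratorConfig(seed=5, n_persons=60, food_archetypes=archetypes,
                            calibrate=False)
        )
        for family in ("moderation", "reformulation"):
            for res in run_sensitivity_suite(dataset, family).values():
                for pct in res.pct_change.values():
                    if pct is not None:
                        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_unknown_family_rejected(self, tiny_dataset):
        with pytest.raises(ScenarioError):
            run_sensitivity_suite(tiny_dataset, "taxation")
        with pytest.raises(ScenarioError):
            ScenarioSpec("taxation").validate()
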