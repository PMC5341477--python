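"""Substitution engine: eligibility rules, isocaloric replacement, audits."""
import numpy as np
import pandas as pd
import pytest

from snacksub import (FoodRecord, exclusive_nut_snacker, is_eligible, model1,
                      model2, run_models, substitute_dataset, substitute_day)
from snacksub.composite import PROFILE_COLS, CompositeProfile
from snacksub.recalls import foods_frame
from snacksub.substitution import eligibility_mask, exclusive_nut_snacker_flags


def record(occasion="snack", category="cookies_brownies", is_beverage=False,
           is_tree_nut=False, wgf=0.0, energy=100.0, person="p", day=1):
    return FoodRecord(person, day, occasion, is_beverage, category, energy,
                      is_tree_nut=is_tree_nut, whole_grain_fraction=wgf)


@pytest.fixture
def simple_composite():
    profile = {c: 0.0 for c in PROFILE_COLS}
    profile.update({"sodium_mg": 0.2, "fiber_g": 2.0, "added_sugars_tsp": 0.0})
    return CompositeProfile("tree_nut", {"x": 1.0}, profile, 5.75)


class TestEligibility:
    def test_popcorn_exempt_under_model2_only(self, simple_composite):
        popcorn = record(category="popcorn", wgf=1.0)
        ok1, _ = is_eligible(popcorn, model1(simple_composite))
        ok2, reason = is_eligible(popcorn, model2(simple_composite))
        assert ok1 and not ok2
        assert reason == "whole_grain_majority"

    def test_apple_exempt_under_model2_only(self, simple_composite):
        apple = record(category="apples")
        assert is_eligible(apple, model1(simple_composite))[0]
        ok, reason = is_eligible(apple, model2(simple_composite))
        assert not ok and reason == "whole_fruit"

    def test_beverages_never_replaced(self, simple_composite):
        cola = record(is_beverage=True, category="other")
        for model in (model1(simple_composite), model2(simple_composite)):
            ok, reason = is_eligible(cola, model)
            assert not ok and reason == "beverage"

    def test_beverage_addition_never_replaced(self, simple_composite):
        sugar = record(occasion="beverage_addition", is_beverage=True,
                       category="other")
        ok, reason = is_eligible(sugar, model1(simple_composite))
        assert not ok and reason == "beverage_addition"

    def test_tree_nut_snacks_not_replaced(self, simple_composite):
        nuts = record(is_tree_nut=True, category="other")
        ok, reason = is_eligible(nuts, model1(simple_composite))
        assert not ok and reason == "tree_nut"

    def test_meals_never_eligible(self, simple_composite):
        meal = record(occasion="meal")
        assert not is_eligible(meal, model1(simple_composite))[0]

    def test_model2_subset_of_model1(self, small_study, simple_composite):
        """Recordwise monotonicity of the eligible sets."""
        _, _, foods, _ = small_study
        m1, _ = eligibility_mask(foods, model1(simple_composite))
        m2, _ = eligibility_mask(foods, model2(simple_composite))
        assert not (m2 & ~m1).any()

    def test_model_constructors_enforce_exemptions(self, simple_composite):
        from snacksub.substitution import SubstitutionModel
        with pytest.raises(ValueError):
            SubstitutionModel("model1", simple_composite,
                              frozenset({"whole_fruit"}))
        with pytest.raises(ValueError):
            SubstitutionModel("model2", simple_composite, frozenset())


class TestExclusiveNutSnacker:
    def test_only_nut_snacks(self):
        df = foods_frame([record(is_tree_nut=True, category="other"),
                          record(occasion="meal")])
        assert exclusive_nut_snacker(df)

    def test_mixed_snacks(self):
        df = foods_frame([record(is_tree_nut=True, category="other"),
                          record(category="cookies_brownies", day=2)])
        assert not exclusive_nut_snacker(df)

    def test_no_snacks_not_exempt(self):
        df = foods_frame([record(occasion="meal")])
        assert not exclusive_nut_snacker(df)

    def test_snack_beverages_disregarded(self):
        df = foods_frame([record(is_tree_nut=True, category="other"),
                          record(is_beverage=True, category="other")])
        assert exclusive_nut_snacker(df)

    def test_flags_match_rowwise_definition(self, small_study):
        _, _, foods, _ = small_study
        flags = exclusive_nut_snacker_flags(foods)
        for pid in foods["person_id"].unique()[:50]:
            expected = exclusive_nut_snacker(foods[foods["person_id"] == pid])
            assert flags[pid] == expected


class TestSubstituteDay:
    def test_linear_scaling_and_energy_conservation(self, simple_composite):
        day = foods_frame([record(energy=150.0),
                           record(occasion="meal", energy=500.0)])
        res = substitute_day(day, model1(simple_composite))
        assert res.replaced_energy_kcal == 150.0
        assert res.records["energy_kcal"].sum() == day["energy_kcal"].sum()
        comp = res.records[res.records["is_tree_nut"]]
        assert comp["sodium_mg"].iloc[0] == pytest.approx(0.3)
        assert comp["fiber_g"].iloc[0] == pytest.approx(3.0)

    def test_no_eligible_energy_is_identity(self, simple_composite):
        day = foods_frame([record(occasion="meal", energy=500.0)])
        res = substitute_day(day, model1(simple_composite))
        pd.testing.assert_frame_equal(res.records, day)
        assert res.replaced_energy_kcal == 0.0

    def test_exempt_person_passthrough(self, simple_composite):
        day = foods_frame([record(energy=200.0)])
        res = substitute_day(day, model1(simple_composite), exempt=True)
        pd.testing.assert_frame_equal(res.records, day)
        assert all(r == "exclusive_nut_snacker" for _, _, r in res.audit)


class TestSubstituteDataset:
    def test_energy_conserved_per_person_day(self, small_study, all_models):
        _, _, foods, _ = small_study
        before = foods.groupby(["person_id", "recall_day"])["energy_kcal"].sum()
        for model in all_models.values():
            modified, _ = substitute_dataset(foods, model)
            after = modified.groupby(["person_id", "recall_day"])["energy_kcal"].sum()
            diff = (after - before).abs() / before
            assert diff.max() < 1e-9

    def test_meals_untouched(self, small_study, all_models):
        _, _, foods, _ = small_study
        meals = foods[foods["occasion"] == "meal"].reset_index(drop=True)
        for model in all_models.values():
            modified, _ = substitute_dataset(foods, model)
            meals2 = (modified[modified["occasion"] == "meal"]
                      .reset_index(drop=True))
            pd.testing.assert_frame_equal(meals, meals2)

    def test_idempotence(self, small_study, all_models):
        """Substituting an already-substituted dataset is a fixed point."""
        _, _, foods, _ = small_study
        model = all_models["model1_tree_nut"]
        once, _ = substitute_dataset(foods, model)
        twice, audit = substitute_dataset(once, model)
        assert not audit["eligible"].any()
        key = ["person_id", "recall_day"]
        pd.testing.assert_frame_equal(
            once.sort_values(key + ["energy_kcal"]).reset_index(drop=True),
            twice.sort_values(key + ["energy_kcal"]).reset_index(drop=True))

    def test_modified_totals_match_naive_oracle(self, small_study, all_models):
        """Sodium and added-sugar day totals equal a naive re-summation."""
        _, _, foods, _ = small_study
        model = all_models["model2_tree_nut"]
        modified, audit = substitute_dataset(foods, model)
        got = (modified.groupby(["person_id", "recall_day"])
               [["sodium_mg", "added_sugars_tsp"]].sum())
        # oracle: start from originals, remove eligible, add composite share
        per100 = model.composite.per_100kcal
        expected = {}
        for _, row in foods.iterrows():
            key = (row["person_id"], row["recall_day"])
            acc = expected.setdefault(key, [0.0, 0.0])
            arow = audit.loc[row.name]
            if arow["eligible"]:
                scale = row["energy_kcal"] / 100.0
                acc[0] += per100["sodium_mg"] * scale
                acc[1] += per100["added_sugars_tsp"] * scale
            else:
                acc[0] += row["sodium_mg"]
                acc[1] += row["added_sugars_tsp"]
        for key, (na, sug) in expected.items():
            assert got.loc[key, "sodium_mg"] == pytest.approx(na, rel=1e-9)
            assert got.loc[key, "added_sugars_tsp"] == pytest.approx(sug, rel=1e-9)


class TestRunModels:
    def test_all_meal_dataset_unchanged(self, all_models, small_study):
        _, persons, foods, _ = small_study
        meals = foods[foods["occasion"] == "meal"]
        persons = persons[persons["person_id"].isin(meals["person_id"])]
        out = run_models(meals, persons, all_models)
        for res in out.values():
            assert len(res["foods"]) == len(meals)
            assert not res["audit"]["eligible"].any()

    def test_replaced_energy_age_gradient(self, composite_tree):
        """Older adults snack least, so replaced energy falls with age."""
        from snacksub import GeneratorConfig, generate_dataset
        persons, foods, _ = generate_dataset(
            GeneratorConfig(n_persons=3000, seed=9))
        out = run_models(foods, persons, {"m1": model1(composite_tree)})
        by_age = out["m1"]["replaced_by_age"]
        assert by_age["20-30"] > by_age["71+"]
        assert by_age["31-50"] > by_age["71+"]
        assert by_age["51-70"] > by_age["71+"]
        assert max(by_age["20-30"], by_age["31-50"]) > by_age["51-70"]
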