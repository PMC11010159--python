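"""Scenario engines: eligibility, addition arithmetic, equal-proportions
removal, permutation invariance, bulk-vs-per-recall consistency."""

import pandas as pd
import pytest

from dietshift.metrics import event_intakes
from dietshift.nutrients import ENERGY, MAR_PANEL
from dietshift.recall_data import PUREE_NO_ADDED_SUGAR, ValidationError
from dietshift.simulation import (
    GRAMS_MODE,
    SIM_FOOD_CODE,
    allocate_removals,
    find_replaceables,
    is_eligible,
    run_occasion_scenarios,
    simulate_addition,
    simulate_isoportion,
)
from dietshift.synthetic import GeneratorConfig, generate_dataset

from conftest import make_events, manual_serving_table

TABLE = manual_serving_table()  # puree serving 90 g everywhere
AG = "4-6"


class TestEligibility:
    def test_no_puree_is_eligible(self):
        ev = make_events([("c", "r", "Breakfast", "other", 200)])
        assert is_eligible(ev, "breakfast", TABLE, AG)

    def test_exactly_one_serving_is_not_eligible(self):
        """'Less than one serving' is strict."""
        ev = make_events([("c", "r", "Breakfast", PUREE_NO_ADDED_SUGAR, 90)])
        assert not is_eligible(ev, "breakfast", TABLE, AG)

    def test_added_sugar_puree_counts_towards_the_serving(self):
        ev = make_events([("c", "r", "Breakfast", "fruit_puree_added_sugar", 30)])
        assert is_eligible(ev, "breakfast", TABLE, AG)
        ev_full = make_events([("c", "r", "Breakfast", "fruit_puree_added_sugar", 90)])
        assert not is_eligible(ev_full, "breakfast", TABLE, AG)


class TestAddition:
    def test_empty_occasion_gets_a_full_serving(self, standard):
        ev = make_events([("c", "r", "Lunch", "other", 300)])
        out = simulate_addition(ev, "breakfast", TABLE, standard, AG)
        assert out.eligible and out.grams_added == 90
        added = out.events[out.events["food_code"] == SIM_FOOD_CODE]
        assert len(added) == 1
        assert added["category"].iloc[0] == PUREE_NO_ADDED_SUGAR
        assert added["occasion_group"].iloc[0] == "breakfast"
        assert out.energy_delta_kcal == pytest.approx(0.9 * standard.composition[ENERGY])

    def test_partial_puree_is_topped_up_to_the_serving(self, standard):
        ev = make_events([("c", "r", "Breakfast", "fruit_puree_added_sugar", 30)])
        out = simulate_addition(ev, "breakfast", TABLE, standard, AG)
        assert out.grams_added == 60

    def test_full_serving_leaves_the_recall_unchanged(self, standard):
        ev = make_events([("c", "r", "Breakfast", PUREE_NO_ADDED_SUGAR, 90)])
        out = simulate_addition(ev, "breakfast", TABLE, standard, AG)
        assert not out.eligible
        pd.testing.assert_frame_equal(out.events, ev)

    def test_non_puree_events_are_untouched(self, standard):
        ev = make_events(
            [("c", "r", "Breakfast", "other", 250), ("c", "r", "Lunch", "biscuit", 40)]
        )
        out = simulate_addition(ev, "breakfast", TABLE, standard, AG)
        pd.testing.assert_frame_equal(out.events.iloc[: len(ev)], ev)


class TestFindReplaceables:
    def test_juice_and_biscuit_are_both_returned(self):
        ev = make_events(
            [
                ("c", "r", "Snack", "fruit_juice", 200),
                ("c", "r", "Snack", "biscuit", 40),
                ("c", "r", "Snack", "other", 100),
            ]
        )
        assert sorted(find_replaceables(ev, "snack")["category"]) == ["biscuit", "fruit_juice"]

    def test_plain_foods_yield_an_empty_list(self):
        ev = make_events([("c", "r", "Snack", "other", 200)])
        assert len(find_replaceables(ev, "snack")) == 0

    def test_added_sugar_puree_is_not_replaceable(self):
        ev = make_events([("c", "r", "Snack", "fruit_puree_added_sugar", 100)])
        assert len(find_replaceables(ev, "snack")) == 0


class TestIsoportionAllocation:
    def test_single_item_loses_one_full_serving(self, standard):
        ev = make_events([("c", "r", "Snack", "soft_drink", 330)])
        out = simulate_isoportion(ev, "snack", TABLE, standard, AG)
        assert out.removed_by_category == {"soft_drink": 250.0}
        drink = out.events[out.events["category"] == "soft_drink"]
        assert drink["amount_g"].iloc[0] == pytest.approx(80)

    def test_two_items_split_the_serving_equally(self, standard):
        """f=1, k=2: juice target 150/2 = 75 g, biscuit target 50/2 = 25 g."""
        ev = make_events(
            [("c", "r", "Snack", "fruit_juice", 200), ("c", "r", "Snack", "biscuit", 40)]
        )
        out = simulate_isoportion(ev, "snack", TABLE, standard, AG)
        assert out.removed_by_category == {"fruit_juice": 75.0, "biscuit": 25.0}

    def test_insufficient_item_is_entirely_removed_without_touching_the_puree(self, standard):
        ev = make_events([("c", "r", "Snack", "ice_cream", 30)])
        out = simulate_isoportion(ev, "snack", TABLE, standard, AG)
        assert out.removed_by_category == {"ice_cream": 30.0}
        assert out.grams_added == 90  # unchanged by the shortfall
        assert out.events[out.events["category"] == "ice_cream"]["amount_g"].iloc[0] == 0

    def test_partial_puree_prorates_the_removal(self, standard):
        # 30 g puree present -> f = 60/90 = 2/3; single drink target 2/3 * 250
        ev = make_events(
            [
                ("c", "r", "Snack", "fruit_puree_added_sugar", 30),
                ("c", "r", "Snack", "soft_drink", 330),
            ]
        )
        out = simulate_isoportion(ev, "snack", TABLE, standard, AG)
        assert out.removed_by_category["soft_drink"] == pytest.approx(2 / 3 * 250)

    def test_no_replaceables_flags_a_skipped_substitution(self, standard):
        ev = make_events([("c", "r", "Snack", "other", 200)])
        out = simulate_isoportion(ev, "snack", TABLE, standard, AG)
        assert out.eligible and out.skipped
        assert (out.events["food_code"] == SIM_FOOD_CODE).sum() == 1  # keeps the addition

    def test_ineligible_recall_is_identity(self, standard):
        ev = make_events([("c", "r", "Snack", PUREE_NO_ADDED_SUGAR, 90)])
        out = simulate_isoportion(ev, "snack", TABLE, standard, AG)
        assert not out.eligible and not out.skipped
        pd.testing.assert_frame_equal(out.events, ev)

    def test_removal_is_prorated_across_events_of_one_category(self, standard):
        ev = make_events(
            [("c", "r", "Snack", "biscuit", 30), ("c", "r", "Snack", "biscuit", 90)]
        )
        out = simulate_isoportion(ev, "snack", TABLE, standard, AG)
        # one merged biscuit item, f=1, k=1 -> remove 50 g, split 1:3
        assert out.removed_by_category == {"biscuit": 50.0}
        amounts = sorted(out.events[out.events["category"] == "biscuit"]["amount_g"])
        assert amounts == [pytest.approx(30 - 12.5), pytest.approx(90 - 37.5)]

    def test_event_order_never_changes_the_allocation(self, standard):
        rows = [
            ("c", "r", "Snack", "fruit_juice", 200),
            ("c", "r", "Snack", "biscuit", 40),
            ("c", "r", "Snack", "soft_drink", 100),
        ]
        base = simulate_isoportion(make_events(rows), "snack", TABLE, standard, AG)
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            out = simulate_isoportion(
                make_events([rows[i] for i in perm]), "snack", TABLE, standard, AG
            )
            assert out.removed_by_category == base.removed_by_category

    def test_grams_mode_removes_the_grams_added(self, standard):
        removed = allocate_removals(
            {"fruit_juice": 200.0, "biscuit": 40.0},
            f=1.0,
            item_servings={"fruit_juice": 150.0, "biscuit": 50.0},
            grams_added=90.0,
            mode=GRAMS_MODE,
        )
        assert removed == {"fruit_juice": 45.0, "biscuit": 40.0}

    def test_invalid_added_fraction_is_rejected(self):
        with pytest.raises(ValidationError):
            allocate_removals({"biscuit": 40.0}, f=1.5, item_servings={"biscuit": 50.0})


@pytest.fixture(scope="module")
def scenarios(standard):
    ds = generate_dataset(GeneratorConfig(n_children=80), seed=11)
    from dietshift.portioning import build_serving_table

    table = build_serving_table(ds)
    return ds, table, run_occasion_scenarios(ds, table, standard, "snack")


class TestBulkEngine:
    def test_bulk_matches_per_recall_simulation(self, scenarios, standard):
        ds, table, scen = scenarios
        recalls = ds.recalls()
        sample = recalls.sample(25, random_state=0)
        audit = scen.audit.set_index(["child_id", "recall_id"])
        for row in sample.itertuples(index=False):
            ev = ds.events[
                (ds.events["child_id"] == row.child_id)
                & (ds.events["recall_id"] == row.recall_id)
            ].reset_index(drop=True)
            add = simulate_addition(ev, "snack", table, standard, row.age_group)
            iso = simulate_isoportion(ev, "snack", table, standard, row.age_group)
            arow = audit.loc[(row.child_id, row.recall_id)]
            assert bool(arow["eligible"]) == add.eligible
            assert arow["grams_added"] == pytest.approx(add.grams_added)
            assert arow["energy_delta_addition_kcal"] == pytest.approx(add.energy_delta_kcal)
            assert arow["energy_delta_isoportion_kcal"] == pytest.approx(
                iso.energy_delta_kcal, abs=1e-9
            )
            for cat, rem in iso.removed_by_category.items():
                assert arow[f"removed_{cat}_g"] == pytest.approx(rem)

    def test_addition_is_componentwise_monotone(self, scenarios):
        ds, _, scen = scenarios
        keys = ["child_id", "recall_id"]
        obs = event_intakes(scen.events_observed).groupby(keys)[MAR_PANEL + [ENERGY]].sum()
        add = event_intakes(scen.events_addition).groupby(keys)[MAR_PANEL + [ENERGY]].sum()
        diff = add - obs
        assert (diff.to_numpy() >= -1e-12).all()

    def test_isoportion_energy_never_exceeds_addition(self, scenarios):
        ds, _, scen = scenarios
        keys = ["child_id", "recall_id"]
        add = event_intakes(scen.events_addition).groupby(keys)[ENERGY].sum()
        iso = event_intakes(scen.events_isoportion).groupby(keys)[ENERGY].sum()
        assert (iso <= add + 1e-9).all()

    def test_other_occasions_are_bit_identical(self, scenarios):
        ds, _, scen = scenarios
        mask = scen.events_observed["occasion_group"] != "snack"
        pd.testing.assert_frame_equal(
            scen.events_isoportion.loc[mask.index[mask]], scen.events_observed.loc[mask]
        )
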