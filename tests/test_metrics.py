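"""Intake aggregation, MAR contract, %E shares, adequacy flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietshift.metrics import (
    adequacy_flags,
    aggregate_intake,
    mar,
    mar_by_child,
    mean_daily_intakes,
    pct_energy,
)
from dietshift.nutrients import ENERGY, ENERGY_FACTORS_KCAL_PER_G, MAR_PANEL, nutrient_vector
from dietshift.recall_data import ValidationError

from conftest import make_events


def recalls_frame(pairs):
    return pd.DataFrame(pairs, columns=["child_id", "recall_id"])


class TestAggregation:
    def test_intake_is_amount_over_100_times_composition(self):
        ev = make_events([("c", "r", "Lunch", "other", 100, {"energy_kcal": 50})])
        out = aggregate_intake(ev, recalls_frame([("c", "r")]), level="recall")
        assert out[ENERGY].iloc[0] == 50

    def test_daily_is_the_mean_over_the_childs_own_recalls(self):
        ev = make_events(
            [
                ("c", "r1", "Lunch", "other", 1000, {"energy_kcal": 180}),
                ("c", "r2", "Lunch", "other", 1000, {"energy_kcal": 200}),
            ]
        )
        out = aggregate_intake(ev, recalls_frame([("c", "r1"), ("c", "r2")]), level="daily")
        assert out[ENERGY].iloc[0] == 1900

    def test_recall_without_the_occasion_counts_as_zero(self):
        ev = make_events([("c", "r1", "Snack", "other", 100, {"energy_kcal": 100})])
        out = mean_daily_intakes(
            ev, recalls_frame([("c", "r1"), ("c", "r2")]), occasion_group="snack"
        )
        assert out[ENERGY].iloc[0] == 50  # 100 kcal on one of two recall days

    def test_occasion_level_linearity_over_disjoint_event_sets(self):
        rows_a = [("c", "r", "Lunch", "other", 150, {"energy_kcal": 120, "proteins_g": 5})]
        rows_b = [("c", "r", "Lunch", "fresh_fruit", 80, {"energy_kcal": 55, "fibres_g": 2})]
        rec = recalls_frame([("c", "r")])
        a = aggregate_intake(make_events(rows_a), rec, level="recall")
        b = aggregate_intake(make_events(rows_b), rec, level="recall")
        ab = aggregate_intake(make_events(rows_a + rows_b), rec, level="recall")
        lhs = ab[MAR_PANEL + [ENERGY]].iloc[0]
        rhs = a[MAR_PANEL + [ENERGY]].iloc[0] + b[MAR_PANEL + [ENERGY]].iloc[0]
        assert np.allclose(lhs, rhs)


class TestMar:
    def test_all_nutrients_at_reference_scores_100(self, refs):
        intake = nutrient_vector({n: refs.lookup(n, "4-6").value for n in MAR_PANEL})
        assert mar(intake, refs, "4-6") == 100

    def test_excess_cannot_compensate_shortfall(self, refs):
        amounts = {n: refs.lookup(n, "4-6").value for n in MAR_PANEL}
        amounts["vitamin_c_mg"] *= 2  # 200 % of reference still counts as 100
        assert mar(nutrient_vector(amounts), refs, "4-6") == 100

    def test_uniform_half_reference_scores_50(self, refs):
        intake = nutrient_vector({n: 0.5 * refs.lookup(n, "4-6").value for n in MAR_PANEL})
        assert mar(intake, refs, "4-6") == pytest.approx(50)

    def test_half_zero_half_at_reference_scores_50(self, refs):
        amounts = {
            n: (refs.lookup(n, "4-6").value if i < 11 else 0.0)
            for i, n in enumerate(MAR_PANEL)
        }
        assert mar(nutrient_vector(amounts), refs, "4-6") == pytest.approx(100 * 11 / 22)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 3, allow_nan=False), min_size=22, max_size=22),
        st.integers(0, 21),
        st.floats(0.01, 5, allow_nan=False),
    )
    def test_mar_is_monotone_and_jointly_scale_invariant(self, refs, fractions, bump_i, extra):
        base_ref = {n: refs.lookup(n, "7-10").value for n in MAR_PANEL}
        amounts = {n: f * base_ref[n] for n, f in zip(MAR_PANEL, fractions)}
        m0 = mar(nutrient_vector(amounts), refs, "7-10")
        assert 0 <= m0 <= 100
        bumped = dict(amounts)
        bumped[MAR_PANEL[bump_i]] += extra
        assert mar(nutrient_vector(bumped), refs, "7-10") >= m0 - 1e-12

    def test_vectorised_mar_matches_scalar(self, refs, small_dataset):
        daily = mean_daily_intakes(small_dataset.events, small_dataset.recalls())
        daily = daily.merge(
            small_dataset.children[["child_id", "age_group"]], on="child_id"
        ).head(20)
        vec = mar_by_child(daily, daily["age_group"], refs)
        for i in range(len(daily)):
            scalar = mar(daily.iloc[i][MAR_PANEL], refs, daily["age_group"].iloc[i])
            assert vec.iloc[i] == pytest.approx(scalar, abs=1e-12)


class TestPctEnergy:
    def test_free_sugars_share(self):
        assert pct_energy(25, 2000, 4) == pytest.approx(5)

    def test_zero_nutrient_is_zero_share(self):
        assert pct_energy(0, 1234, 9) == 0

    def test_zero_energy_is_an_error(self):
        with pytest.raises(ValidationError):
            pct_energy(10, 0, 4)


class TestAdequacyFlags:
    @staticmethod
    def daily_frame(refs, **overrides):
        amounts = {n: refs.lookup(n, "7-10").value for n in MAR_PANEL}
        amounts[ENERGY] = 1800.0
        amounts.update(
            sfa_g=1800 * 0.10 / 9, free_sugars_g=1800 * 0.08 / 4,
            added_sugars_g=30, sodium_mg=1500, carbohydrates_g=1800 * 0.5 / 4,
            total_fat_g=60,
        )
        amounts.update(overrides)
        frame = pd.DataFrame([amounts])
        frame.insert(0, "child_id", ["c"])
        return frame

    def test_fibre_above_the_floor_is_adequate(self, refs):
        daily = self.daily_frame(refs, fibres_g=18.0)  # floor at 7-10 y is 16 g
        flags = adequacy_flags(daily, pd.Series(["7-10"]), refs)
        assert bool(flags["fibres_g"].iloc[0])

    def test_sfa_above_the_ceiling_is_inadequate(self, refs):
        daily = self.daily_frame(refs, sfa_g=1800 * 0.14 / 9)  # 14 %E vs 12 %E ceiling
        flags = adequacy_flags(daily, pd.Series(["7-10"]), refs)
        assert not bool(flags["sfa_g"].iloc[0])

    def test_boundary_values_count_as_adequate(self, refs):
        daily = self.daily_frame(
            refs, fibres_g=16.0, sfa_g=1800 * 0.12 / 9, free_sugars_g=1800 * 0.10 / 4
        )
        flags = adequacy_flags(daily, pd.Series(["7-10"]), refs)
        assert flags[["fibres_g", "sfa_g", "free_sugars_g"]].iloc[0].all()

    def test_carbohydrates_outside_the_range_are_inadequate(self, refs):
        low = self.daily_frame(refs, carbohydrates_g=1800 * 0.30 / 4)
        high = self.daily_frame(refs, carbohydrates_g=1800 * 0.60 / 4)
        for frame in (low, high):
            flags = adequacy_flags(frame, pd.Series(["7-10"]), refs)
            assert not bool(flags["carbohydrates_g"].iloc[0])

    def test_flags_match_brute_force_rule_evaluation(self, refs):
        """Randomised intakes re-checked against a from-scratch evaluation."""
        rng = np.random.default_rng(3)
        n = 1000
        groups = rng.choice(["1-3", "4-6", "7-10", "11-14", "15-17"], size=n)
        cols = {n_: np.zeros(n) for n_ in MAR_PANEL}
        for nut in MAR_PANEL:
            ref = np.array([refs.lookup(nut, g).value for g in groups])
            cols[nut] = ref * rng.uniform(0, 2, size=n)
        daily = pd.DataFrame(cols)
        daily[ENERGY] = rng.uniform(800, 3000, size=n)
        daily["sfa_g"] = daily[ENERGY] * rng.uniform(0.05, 0.2, n) / 9
        daily["free_sugars_g"] = daily[ENERGY] * rng.uniform(0.02, 0.2, n) / 4
        daily["carbohydrates_g"] = daily[ENERGY] * rng.uniform(0.3, 0.65, n) / 4
        daily["added_sugars_g"] = 0.0
        daily["sodium_mg"] = 0.0
        daily["total_fat_g"] = 0.0
        flags = adequacy_flags(daily, pd.Series(groups), refs)
        for i in rng.choice(n, size=200, replace=False):
            g = groups[i]
            row = daily.iloc[i]
            for nut in [*MAR_PANEL, "sfa_g", "free_sugars_g", "carbohydrates_g"]:
                e = refs.lookup(nut, g)
                if e.basis == "percent_of_energy":
                    val = 100 * row[nut] * ENERGY_FACTORS_KCAL_PER_G[nut] / row[ENERGY]
                else:
                    val = row[nut]
                if e.direction == "floor":
                    expect = val >= e.value
                elif e.direction == "ceiling":
                    expect = val <= e.value
                else:
                    expect = e.low <= val <= e.high
                assert bool(flags[nut].iloc[i]) == expect, (nut, g)
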