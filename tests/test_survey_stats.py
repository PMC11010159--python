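"""Weighted estimators and their classical reductions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietshift.recall_data import ValidationError
from dietshift.survey_stats import (
    categorical_group_test,
    compare_consumer_groups,
    kish_ess,
    paired_shift_test,
    prevalence_test,
    weighted_mean,
    weighted_prevalence,
    weighted_two_sample_test,
)
from dietshift.synthetic import GeneratorConfig, generate_dataset


class TestWeightedMean:
    def test_equal_weights(self):
        assert weighted_mean([1, 3], [1, 1]) == 2

    def test_unequal_weights(self):
        assert weighted_mean([1, 3], [3, 1]) == 1.5

    def test_single_value_identity(self):
        assert weighted_mean([7.5], [0.3]) == 7.5

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValidationError):
            weighted_mean([], [])

    def test_nonpositive_weights_are_rejected(self):
        with pytest.raises(ValidationError):
            weighted_mean([1, 2], [1, 0])


class TestWeightedPrevalence:
    def test_all_true(self):
        assert weighted_prevalence([True, True], [1, 2]) == 100

    def test_weighted_quarter(self):
        assert weighted_prevalence([True, False], [1, 3]) == 25

    def test_all_false(self):
        assert weighted_prevalence([False, False], [2, 1]) == 0


class TestPairedShiftTest:
    def test_all_zero_deltas_is_a_no_shift(self):
        r = paired_shift_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1, 1, 1])
        assert (r.estimate, r.pvalue, r.note) == (0.0, 1.0, "no-shift")

    def test_constant_positive_shift_is_significant(self):
        before = np.zeros(50)
        r = paired_shift_test(before, before + 1.0, np.ones(50))
        assert r.estimate == 1.0
        assert r.pvalue < 0.05

    def test_symmetric_shifts_have_zero_estimate(self):
        before = np.zeros(10)
        after = np.array([1.0, -1.0] * 5)
        r = paired_shift_test(before, after, np.ones(10))
        assert r.estimate == 0.0

    def test_equal_weights_reduce_to_classical_one_sample_t(self):
        rng = np.random.default_rng(5)
        before, after = rng.normal(size=40), rng.normal(size=40) + 0.3
        r = paired_shift_test(before, after, np.ones(40))
        ref = stats.ttest_rel(after, before)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_weight_splitting_leaves_the_estimate_unchanged(self):
        """Replicating every child k times at weight/k preserves all weighted
        estimates (the effective sample size, by design, sees the replicates
        as genuinely independent observations)."""
        rng = np.random.default_rng(6)
        deltas = rng.normal(0.2, 1, size=30)
        w = rng.uniform(0.5, 2, size=30)
        base = paired_shift_test(np.zeros(30), deltas, w)
        k = 3
        split = paired_shift_test(
            np.zeros(30 * k), np.repeat(deltas, k), np.repeat(w / k, k)
        )
        assert split.estimate == pytest.approx(base.estimate, abs=1e-12)
        assert weighted_mean(np.repeat(deltas, k), np.repeat(w / k, k)) == pytest.approx(
            weighted_mean(deltas, w), abs=1e-12
        )


class TestPrevalenceTest:
    def test_identical_flags_give_statistic_zero(self):
        flags = np.array([True, False, True, True])
        r = prevalence_test(flags, flags, np.ones(4))
        assert (r.statistic, r.pvalue) == (0.0, 1.0)

    def test_large_shift_is_significant(self):
        n = 200
        before = np.arange(n) < 40  # 20 %
        after = np.arange(n) < 160  # 80 %
        r = prevalence_test(before, after, np.ones(n))
        assert r.statistic > 0 and r.pvalue < 0.05

    def test_equal_weights_reduce_to_pearson_chi_square(self):
        rng = np.random.default_rng(7)
        before = rng.random(150) < 0.4
        after = rng.random(150) < 0.55
        r = prevalence_test(before, after, np.ones(150))
        table = np.array(
            [[np.sum(~before), np.sum(before)], [np.sum(~after), np.sum(after)]]
        )
        ref = stats.chi2_contingency(table, correction=False)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tiny_sample_does_not_crash(self):
        r = prevalence_test([True, False], [False, True], [1.0, 1.0])
        assert 0 <= r.pvalue <= 1

    def test_degenerate_all_true_table_is_flagged(self):
        flags = np.ones(10, dtype=bool)
        r = prevalence_test(flags, flags, np.ones(10))
        assert r.pvalue == 1.0 and "degenerate" in r.note


def test_kish_ess_equals_n_for_equal_weights():
    assert kish_ess(np.full(17, 2.5)) == pytest.approx(17)


def test_two_sample_test_reduces_to_welch(refs=None):
    rng = np.random.default_rng(8)
    x1, x2 = rng.normal(size=30), rng.normal(0.5, 1.2, size=40)
    r = weighted_two_sample_test(x1, np.ones(30), x2, np.ones(40))
    ref = stats.ttest_ind(x2, x1, equal_var=False)
    assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert r.pvalue == pytest.approx(ref.pvalue, abs=1e-10)


class TestConsumerProfile:
    def test_planted_age_gradient_is_detected(self, refs):
        ds = generate_dataset(GeneratorConfig(n_children=400), seed=2)
        profile = compare_consumer_groups(ds, refs)
        age_rows = profile.sociodemo[profile.sociodemo["variable"] == "age_group"]
        assert (age_rows["pvalue"] < 0.05).all()
        # consumers skew young by construction
        young = age_rows[age_rows["level"] == "1-3"].iloc[0]
        assert young["pct_consumers"] > young["pct_non_consumers"]
        edu = profile.sociodemo[profile.sociodemo["variable"] == "education"]
        high = edu[edu["level"] == "higher"].iloc[0]
        assert high["pct_consumers"] > high["pct_non_consumers"]

    def test_identical_groups_show_no_differences(self):
        """Duplicated children relabelled as the two groups: the null case."""
        from dietshift.recall_data import dataset_from_frames
        from dietshift.synthetic import GeneratorConfig, generate_food_table, generate_population

        cfg = GeneratorConfig(n_children=30, sociodemo_gradient=False)
        roster = generate_population(cfg, seed=9)
        food = generate_food_table(cfg)
        from dietshift.synthetic import generate_recalls

        events = generate_recalls(roster, food, cfg, seed=9,
                                  planted_consumers=pd.Series(False, index=roster.index))
        # clone every child; clones consume puree, originals do not
        clones = roster.copy()
        clones["child_id"] = clones["child_id"] + "X"
        ev_clone = events.copy()
        ev_clone["child_id"] = ev_clone["child_id"] + "X"
        ev_clone["recall_id"] = ev_clone["recall_id"].str.replace("-R", "X-R")
        puree = ev_clone.groupby("child_id").head(1).copy()
        puree["category"] = "fruit_puree_no_added_sugar"
        puree["amount_g"] = 90.0
        ds = dataset_from_frames(
            pd.concat([roster, clones], ignore_index=True),
            pd.concat([events, ev_clone, puree], ignore_index=True),
        )
        profile = compare_consumer_groups(ds)
        socio = profile.sociodemo.dropna(subset=["pvalue"])
        assert (socio["pvalue"] > 0.05).all()

    def test_single_child_group_gets_missing_test_markers(self):
        labels = pd.Series(["a", "b", "a", "b"])
        group = np.array([True, False, False, False])
        r = categorical_group_test(labels, group, np.ones(4))
        assert np.isnan(r.pvalue) and r.note == "group too small"
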