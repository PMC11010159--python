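"""Survey-weighted descriptive and inferential statistics.

All estimators take per-child survey weights correcting unequal sampling
probability and non-response.  Inference uses the effective sample size of
Kish, ``ESS = (sum w)^2 / sum w^2``:

* the paired-shift test is a weighted one-sample t-test on per-child deltas
  (simulated minus observed) against zero, with the weighted variance scaled
  by ESS;
* the prevalence comparison is a Pearson chi-square on the weighted 2x2
  table rescaled to the nominal sample sizes, divided by the Kish design
  effect (a first-order Rao-Scott-style correction).

With all weights equal both reduce exactly to the classical unweighted tests.
No multiple-testing correction is applied; every comparison is read at the
flat 5 % level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recall_data import ValidationError


@dataclass
class WeightedSample:
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise ValidationError("values and weights must have equal length")
        if len(self.weights) == 0:
            raise ValidationError("empty weighted sample")
        if (self.weights <= 0).any():
            raise ValidationError("weights must be strictly positive")


def weighted_mean(values, weights) -> float:
    s = WeightedSample(values, weights)
    return float(np.average(s.values.astype(float), weights=s.weights))


def weighted_prevalence(flags, weights) -> float:
    """Weighted share of true flags, in percent."""
    s = WeightedSample(np.asarray(flags, dtype=bool), np.asarray(weights))
    return 100.0 * weighted_mean(s.values.astype(float), s.weights)


def kish_ess(weights) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


@dataclass
class ShiftTestResult:
    estimate: float  # weighted mean delta (after - before)
    statistic: float
    pvalue: float
    ess: float
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def paired_shift_test(before, after, weights) -> ShiftTestResult:
    """Weighted one-sample t-test of per-child shifts against zero.

    Degenerate inputs are reported, never raised: all-zero deltas give a
    no-shift result (p = 1); a non-zero constant shift has zero variance and
    is reported as significant with p = 0.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValidationError("before/after must be aligned per child")
    deltas = after - before
    s = WeightedSample(deltas, np.asarray(weights))
    ess = kish_ess(s.weights)
    mean = weighted_mean(deltas, s.weights)
    if np.all(deltas == 0):
        return ShiftTestResult(0.0, 0.0, 1.0, ess, note="no-shift")
    var_w = float(np.average((deltas - mean) ** 2, weights=s.weights))
    if ess <= 1 or var_w == 0:
        if var_w == 0:
            return ShiftTestResult(mean, math.inf, 0.0, ess, note="zero-variance shift")
        return ShiftTestResult(mean, math.nan, math.nan, ess, note="ess<=1")
    var_unbiased = var_w * ess / (ess - 1)
    se = math.sqrt(var_unbiased / ess)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df=ess - 1)
    return ShiftTestResult(mean, t, min(1.0, p), ess)


@dataclass
class PrevalenceTestResult:
    statistic: float
    pvalue: float
    dof: int
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def _rao_scott_chi2(table_props: np.ndarray, n_rows: np.ndarray, deff: float, dof: int) -> PrevalenceTestResult:
    """Pearson chi2 on weighted within-row proportions scaled to nominal n,
    divided by the design effect."""
    counts = table_props * n_rows[:, None]
    total = counts.sum()
    expected = counts.sum(axis=1, keepdims=True) * counts.sum(axis=0, keepdims=True) / total
    if (expected == 0).any():
        return PrevalenceTestResult(0.0, 1.0, dof, note="degenerate table (zero expected cell)")
    x2 = float(((counts - expected) ** 2 / expected).sum())
    x2_adj = x2 / deff
    return PrevalenceTestResult(x2_adj, float(stats.chi2.sf(x2_adj, dof)), dof)


def prevalence_test(flags_before, flags_after, weights, weights_after=None) -> PrevalenceTestResult:
    """Design-weighted chi-square comparison of two adequacy prevalences.

    ``flags_before`` and ``flags_after`` are the same children under the two
    diets (``weights_after`` defaults to ``weights``).  With equal weights the
    statistic equals the classical Pearson chi-square on the 2x2 counts.
    """
    fb = np.asarray(flags_before, dtype=bool)
    fa = np.asarray(flags_after, dtype=bool)
    wb = np.asarray(weights, dtype=float)
    wa = wb if weights_after is None else np.asarray(weights_after, dtype=float)
    WeightedSample(fb, wb)
    WeightedSample(fa, wa)
    props = np.array(
        [
            [1 - weighted_prevalence(fb, wb) / 100, weighted_prevalence(fb, wb) / 100],
            [1 - weighted_prevalence(fa, wa) / 100, weighted_prevalence(fa, wa) / 100],
        ]
    )
    n_rows = np.array([len(fb), len(fa)], dtype=float)
    deff = float(len(np.concatenate([wb, wa])) * (np.concatenate([wb, wa]) ** 2).sum()
                 / np.concatenate([wb, wa]).sum() ** 2)
    return _rao_scott_chi2(props, n_rows, deff, dof=1)


def weighted_two_sample_test(x1, w1, x2, w2) -> ShiftTestResult:
    """Weighted Welch-style comparison of two independent group means."""
    s1, s2 = WeightedSample(np.asarray(x1, float), w1), WeightedSample(np.asarray(x2, float), w2)
    m1, m2 = weighted_mean(s1.values, s1.weights), weighted_mean(s2.values, s2.weights)
    e1, e2 = kish_ess(s1.weights), kish_ess(s2.weights)
    if e1 <= 1 or e2 <= 1:
        return ShiftTestResult(m2 - m1, math.nan, math.nan, min(e1, e2), note="group too small")
    v1 = float(np.average((s1.values - m1) ** 2, weights=s1.weights)) * e1 / (e1 - 1)
    v2 = float(np.average((s2.values - m2) ** 2, weights=s2.weights)) * e2 / (e2 - 1)
    se2 = v1 / e1 + v2 / e2
    if se2 == 0:
        if m1 == m2:
            return ShiftTestResult(0.0, 0.0, 1.0, min(e1, e2), note="no difference")
        return ShiftTestResult(m2 - m1, math.inf, 0.0, min(e1, e2), note="zero-variance groups")
    t = (m2 - m1) / math.sqrt(se2)
    df = se2**2 / ((v1 / e1) ** 2 / (e1 - 1) + (v2 / e2) ** 2 / (e2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return ShiftTestResult(m2 - m1, t, min(1.0, p), min(e1, e2))


def categorical_group_test(labels, group, weights) -> PrevalenceTestResult:
    """Rao-Scott-corrected chi-square for a categorical variable across two
    groups (e.g. consumers vs non-consumers)."""
    labels = pd.Series(np.asarray(labels))
    group = np.asarray(group, dtype=bool)
    w = np.asarray(weights, dtype=float)
    cats = sorted(labels.astype(str).unique())
    labels = labels.astype(str)
    rows = []
    n_rows = []
    for g in (False, True):
        mask = group == g
        if mask.sum() == 0:
            return PrevalenceTestResult(math.nan, math.nan, len(cats) - 1, note="empty group")
        wg = w[mask]
        rows.append([wg[(labels[mask] == c).to_numpy()].sum() / wg.sum() for c in cats])
        n_rows.append(mask.sum())
    if min(n_rows) < 2:
        return PrevalenceTestResult(math.nan, math.nan, len(cats) - 1, note="group too small")
    deff = float(len(w) * (w**2).sum() / w.sum() ** 2)
    return _rao_scott_chi2(np.array(rows), np.array(n_rows, dtype=float), deff, dof=len(cats) - 1)


# ---------------------------------------------------------------------------
# consumer vs non-consumer profiling


@dataclass
class ConsumerComparison:
    sociodemo: pd.DataFrame  # weighted category distributions + chi2 p per variable
    nutrients: pd.DataFrame  # weighted group means + test per quantity


def compare_consumer_groups(dataset, refs=None) -> ConsumerComparison:
    """Profile fruit-puree consumers against non-consumers.

    Sociodemographic variables get weighted distributions and chi-square
    tests; mean fresh-fruit and juice consumption (g/d), added-sugars %E,
    sodium, SFA %E and MAR get weighted means with group-difference tests,
    and fibres are reported by age group because the reference differs by
    age.  Degenerate groups produce missing-test markers, not exceptions.
    """
    from .metrics import mar_by_child, mean_daily_intakes, pct_energy_column
    from .recall_data import consumer_flags

    children = dataset.children.reset_index(drop=True)
    flags = consumer_flags(children, dataset.events).to_numpy()
    w = children["survey_weight"].to_numpy(dtype=float)

    socio_rows = []
    qualitative = ["sex", "age_group", *dataset.sociodemo_columns]
    for var in qualitative:
        test = categorical_group_test(children[var], flags, w)
        for level in sorted(children[var].astype(str).unique()):
            is_level = (children[var].astype(str) == level).to_numpy(dtype=float)
            row = {"variable": var, "level": level, "statistic": test.statistic,
                   "pvalue": test.pvalue, "note": test.note}
            for gname, gmask in (("consumers", flags), ("non_consumers", ~flags)):
                row[f"pct_{gname}"] = (
                    weighted_prevalence(is_level[gmask].astype(bool), w[gmask])
                    if gmask.sum() else math.nan
                )
            socio_rows.append(row)
    sociodemo = pd.DataFrame(socio_rows)

    daily = mean_daily_intakes(dataset.events, dataset.recalls())
    daily = daily.merge(children[["child_id", "age_group", "survey_weight"]], on="child_id")
    daily["consumer"] = consumer_flags(daily, dataset.events).to_numpy()

    # daily grams of fresh fruit / juice need the event table, not nutrients
    grams = (
        dataset.events.groupby(["child_id", "category"])["amount_g"].sum().unstack(fill_value=0.0)
    )
    n_recalls = dataset.recalls().groupby("child_id").size()
    for cat, col in (("fresh_fruit", "fresh_fruit_g_d"), ("fruit_juice", "fruit_juice_g_d")):
        per_day = grams.get(cat, pd.Series(0.0, index=grams.index)) / n_recalls
        daily[col] = daily["child_id"].map(per_day).fillna(0.0)

    daily["added_sugars_pct_e"] = pct_energy_column(daily, "added_sugars_g")
    daily["sfa_pct_e"] = pct_energy_column(daily, "sfa_g")
    if refs is not None:
        daily["mar"] = mar_by_child(daily, daily["age_group"], refs)

    quantities = ["fresh_fruit_g_d", "fruit_juice_g_d", "added_sugars_pct_e",
                  "sodium_mg", "sfa_pct_e"] + (["mar"] if refs is not None else [])
    nut_rows = []

    def _compare(frame: pd.DataFrame, quantity: str, label: str) -> dict:
        cons = frame[frame["consumer"]]
        non = frame[~frame["consumer"]]
        row = {"quantity": label}
        for gname, g in (("consumers", cons), ("non_consumers", non)):
            valid = g[quantity].notna()
            row[f"mean_{gname}"] = (
                weighted_mean(g.loc[valid, quantity], g.loc[valid, "survey_weight"])
                if valid.sum() else math.nan
            )
        c_ok, n_ok = cons[quantity].dropna(), non[quantity].dropna()
        if len(c_ok) >= 2 and len(n_ok) >= 2:
            test = weighted_two_sample_test(
                non.loc[n_ok.index, quantity], non.loc[n_ok.index, "survey_weight"],
                cons.loc[c_ok.index, quantity], cons.loc[c_ok.index, "survey_weight"],
            )
            row.update(statistic=test.statistic, pvalue=test.pvalue, note=test.note)
        else:
            row.update(statistic=math.nan, pvalue=math.nan, note="group too small")
        return row

    for q in quantities:
        nut_rows.append(_compare(daily, q, q))
    for ag in sorted(daily["age_group"].unique()):
        nut_rows.append(_compare(daily[daily["age_group"] == ag], "fibres_g", f"fibres_g[{ag}]"))
    nutrients = pd.DataFrame(nut_rows)
    return ConsumerComparison(sociodemo=sociodemo, nutrients=nutrients)


__all__ = [
    "ConsumerComparison",
    "PrevalenceTestResult",
    "ShiftTestResult",
    "WeightedSample",
    "categorical_group_test",
    "compare_consumer_groups",
    "kish_ess",
    "paired_shift_test",
    "prevalence_test",
    "weighted_mean",
    "weighted_prevalence",
    "weighted_two_sample_test",
]
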