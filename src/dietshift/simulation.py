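"""The two scenario engines: ADDITION and ISOPORTION SUBSTITUTION.

Both scenarios act on one eating occasion of one 24-h recall at a time, and
occasions are simulated successively and independently (never chained), so a
simulated day contains exactly one modified occasion.

* **ADDITION** tops the occasion's fruit-puree amount up to one standard
  serving with a no-added-sugar fruit puree (NASFP) of standard composition,
  removing nothing.  A recall enters the simulation only if it contains
  strictly less than one serving of fruit puree (either subcategory) at that
  occasion.
* **ISOPORTION SUBSTITUTION** starts from ADDITION and compensates by
  removing replaceable sweetened items present at the same occasion.  The
  removal is denominated in servings: if a fraction ``f`` of a puree serving
  was added and ``k`` replaceable items (categories) are present, each item
  loses ``f/k`` of its own standard serving, spread pro-rata over its events.
  An item whose amount falls short of its target is removed entirely, with no
  redistribution to the other items and no change to the puree added.  A
  grams-denominated variant (remove exactly the grams added, split equally)
  is available via ``removal_mode="grams"``.

Recalls that enter ADDITION but have no replaceable item keep the ADDITION
diet in the ISOPORTION scenario and are flagged ``isoportion_skipped`` — the
substitution simply could not be performed there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .nutrients import ALL_NUTRIENTS, COMP_SUFFIX, ENERGY, validate_vector
from .portioning import ServingTable
from .recall_data import (
    CANONICAL_RAW_LABEL,
    DEFAULT_REPLACEABLE_CATEGORIES,
    POOLED_PUREE,
    PUREE_CATEGORIES,
    PUREE_NO_ADDED_SUGAR,
    DietDataset,
    ValidationError,
)

ADDITION = "ADDITION"
ISOPORTION = "ISOPORTION"
OBSERVED = "OBSERVED"
SCENARIOS = (ADDITION, ISOPORTION)

SERVINGS_MODE = "servings"
GRAMS_MODE = "grams"

#: Reserved food code carried by events the simulation itself creates.
SIM_FOOD_CODE = "SIM-NASFP"

_KEYS = ["child_id", "recall_id"]


class StandardNASFP:
    """Per-100 g composition of the standard no-added-sugar fruit puree.

    The accounting treats NASFP as contributing no free and no added sugars
    (its sugars are intrinsic fruit sugars); both components must be zero.
    """

    def __init__(self, composition: pd.Series):
        composition = validate_vector(composition)
        if composition["free_sugars_g"] != 0 or composition["added_sugars_g"] != 0:
            raise ValidationError("standard NASFP must have zero free and added sugars")
        self.composition = composition

    @classmethod
    def from_csv(cls, path: str | Path) -> "StandardNASFP":
        frame = pd.read_csv(path)
        return cls(pd.Series(frame.per100g.values, index=frame.nutrient.values, dtype=float))

    @classmethod
    def default(cls) -> "StandardNASFP":
        path = resources.files("dietshift.data") / "standard_nasfp.csv"
        with resources.as_file(path) as p:
            return cls.from_csv(p)

    def composition_row(self) -> dict[str, float]:
        """Composition as event-table columns (``*_per100g``)."""
        return {n + COMP_SUFFIX: float(self.composition[n]) for n in ALL_NUTRIENTS}


@dataclass
class SimulationOutcome:
    """A modified recall plus an audit of what changed."""

    scenario: str
    occasion_group: str
    child_id: object
    recall_id: object
    eligible: bool
    events: pd.DataFrame
    grams_added: float = 0.0
    removed_by_category: dict[str, float] = field(default_factory=dict)
    energy_delta_kcal: float = 0.0
    skipped: bool = False  # ISOPORTION precondition (no replaceable item) unmet


def _occasion_puree_grams(events: pd.DataFrame, occasion_group: str) -> float:
    mask = (events["occasion_group"] == occasion_group) & events["category"].isin(PUREE_CATEGORIES)
    return float(events.loc[mask, "amount_g"].sum())


def is_eligible(
    events: pd.DataFrame, occasion_group: str, serving_table: ServingTable, age_group: str
) -> bool:
    """Strictly less than one puree serving at the occasion (both subcategories)."""
    serving = serving_table.serving(POOLED_PUREE, age_group, occasion_group)
    return _occasion_puree_grams(events, occasion_group) < serving


def _nasfp_event(
    child_id, recall_id, occasion_group: str, amount_g: float, standard: StandardNASFP,
    template: pd.DataFrame,
) -> pd.DataFrame:
    row = {c: "" for c in template.columns}
    row.update(
        child_id=child_id,
        recall_id=recall_id,
        raw_occasion=CANONICAL_RAW_LABEL[occasion_group],
        occasion_group=occasion_group,
        category=PUREE_NO_ADDED_SUGAR,
        amount_g=amount_g,
        food_code=SIM_FOOD_CODE,
    )
    row.update(standard.composition_row())
    return pd.DataFrame([row], columns=template.columns)


def simulate_addition(
    events: pd.DataFrame,
    occasion_group: str,
    serving_table: ServingTable,
    standard: StandardNASFP,
    age_group: str,
) -> SimulationOutcome:
    """Top puree up to one serving at the occasion; touch nothing else."""
    child_id = events["child_id"].iloc[0] if len(events) else None
    recall_id = events["recall_id"].iloc[0] if len(events) else None
    serving = serving_table.serving(POOLED_PUREE, age_group, occasion_group)
    current = _occasion_puree_grams(events, occasion_group)
    if current >= serving:
        return SimulationOutcome(
            ADDITION, occasion_group, child_id, recall_id, eligible=False, events=events.copy()
        )
    add_g = serving - current
    new_event = _nasfp_event(child_id, recall_id, occasion_group, add_g, standard, events)
    modified = pd.concat([events, new_event], ignore_index=True)
    return SimulationOutcome(
        ADDITION,
        occasion_group,
        child_id,
        recall_id,
        eligible=True,
        events=modified,
        grams_added=add_g,
        energy_delta_kcal=add_g / 100.0 * float(standard.composition[ENERGY]),
    )


def find_replaceables(
    events: pd.DataFrame,
    occasion_group: str,
    replaceable_categories: list[str] | None = None,
) -> pd.DataFrame:
    """Events at the occasion whose category is on the replaceable list.

    The list carries no priority rank: downstream allocation must be invariant
    to the order of the returned rows.
    """
    cats = replaceable_categories or DEFAULT_REPLACEABLE_CATEGORIES
    mask = (
        (events["occasion_group"] == occasion_group)
        & events["category"].isin(cats)
        & (events["amount_g"] > 0)
    )
    return events.loc[mask]


def allocate_removals(
    totals_by_category: dict[str, float],
    f: float,
    item_servings: dict[str, float],
    grams_added: float = 0.0,
    mode: str = SERVINGS_MODE,
) -> dict[str, float]:
    """Grams to remove per replaceable item under the equal-proportions rule.

    ``f`` is the fraction of a puree serving added (in (0, 1]); ``k`` items
    share the removal equally.  In servings mode item ``i``'s target is
    ``(f/k) * serving_i``; in grams mode it is ``grams_added / k``.  An item
    with less than its target is removed entirely (no redistribution).
    """
    if not 0 < f <= 1:
        raise ValidationError(f"added fraction f must be in (0, 1], got {f}")
    k = len(totals_by_category)
    out: dict[str, float] = {}
    for cat, total in totals_by_category.items():
        if mode == SERVINGS_MODE:
            target = (f / k) * item_servings[cat]
        elif mode == GRAMS_MODE:
            target = grams_added / k
        else:
            raise ValidationError(f"unknown removal mode {mode!r}")
        out[cat] = min(total, target)
    return out


def simulate_isoportion(
    events: pd.DataFrame,
    occasion_group: str,
    serving_table: ServingTable,
    standard: StandardNASFP,
    age_group: str,
    removal_mode: str = SERVINGS_MODE,
    replaceable_categories: list[str] | None = None,
) -> SimulationOutcome:
    """ADDITION followed by serving-for-serving removal of replaceable items."""
    added = simulate_addition(events, occasion_group, serving_table, standard, age_group)
    if not added.eligible:
        return SimulationOutcome(
            ISOPORTION, occasion_group, added.child_id, added.recall_id,
            eligible=False, events=events.copy(),
        )
    repl = find_replaceables(events, occasion_group, replaceable_categories)
    if len(repl) == 0:
        return SimulationOutcome(
            ISOPORTION, occasion_group, added.child_id, added.recall_id,
            eligible=True, events=added.events, grams_added=added.grams_added,
            energy_delta_kcal=added.energy_delta_kcal, skipped=True,
        )
    serving = serving_table.serving(POOLED_PUREE, age_group, occasion_group)
    f = added.grams_added / serving
    totals = repl.groupby("category")["amount_g"].sum().to_dict()
    item_servings = {
        cat: serving_table.serving(cat, age_group, occasion_group) for cat in totals
    }
    removed = allocate_removals(totals, f, item_servings, added.grams_added, removal_mode)

    modified = added.events.copy()
    removed_energy = 0.0
    energy_col = ENERGY + COMP_SUFFIX
    for cat, rem in removed.items():
        cat_rows = modified.index[
            (modified["occasion_group"] == occasion_group)
            & (modified["category"] == cat)
            & (modified["amount_g"] > 0)
            & (modified["food_code"] != SIM_FOOD_CODE)
        ]
        amounts = modified.loc[cat_rows, "amount_g"]
        share = amounts / amounts.sum()  # pro-rata over the item's events
        event_removed = share * rem
        modified.loc[cat_rows, "amount_g"] = amounts - event_removed
        removed_energy += float((event_removed * modified.loc[cat_rows, energy_col] / 100.0).sum())
    return SimulationOutcome(
        ISOPORTION,
        occasion_group,
        added.child_id,
        added.recall_id,
        eligible=True,
        events=modified,
        grams_added=added.grams_added,
        removed_by_category=removed,
        energy_delta_kcal=added.energy_delta_kcal - removed_energy,
    )


# ---------------------------------------------------------------------------
# vectorised engine over a whole dataset


@dataclass
class OccasionScenarios:
    """All recalls' ADDITION and ISOPORTION diets for one eating occasion."""

    occasion_group: str
    events_observed: pd.DataFrame
    events_addition: pd.DataFrame
    events_isoportion: pd.DataFrame
    audit: pd.DataFrame  # one row per recall


def run_occasion_scenarios(
    dataset: DietDataset,
    serving_table: ServingTable,
    standard: StandardNASFP,
    occasion_group: str,
    removal_mode: str = SERVINGS_MODE,
) -> OccasionScenarios:
    """Apply both scenarios to every recall at one occasion (vectorised).

    Produces full event tables (all occasions, the target one modified) for
    each scenario plus a per-recall audit: eligibility, grams of NASFP added,
    per-category grams removed, and the energy deltas.  Recalls are treated
    independently; events at other occasions are bit-identical to observed.
    """
    events = dataset.events
    recalls = dataset.recalls()
    repl_cats = dataset.config.replaceable_categories

    occ_mask = events["occasion_group"] == occasion_group
    puree_g = (
        events.loc[occ_mask & events["category"].isin(PUREE_CATEGORIES)]
        .groupby(_KEYS)["amount_g"]
        .sum()
    )
    audit = recalls.copy()
    audit["puree_g"] = (
        audit.set_index(_KEYS).index.map(puree_g).to_numpy(dtype=float, na_value=0.0)
    )
    nasfp_serving = {
        ag: serving_table.serving(POOLED_PUREE, ag, occasion_group)
        for ag in audit["age_group"].unique()
    }
    audit["serving_g"] = audit["age_group"].map(nasfp_serving)
    audit["eligible"] = audit["puree_g"] < audit["serving_g"]
    audit["grams_added"] = np.where(audit["eligible"], audit["serving_g"] - audit["puree_g"], 0.0)

    # --- ADDITION: one standard-composition event per eligible recall
    elig = audit[audit["eligible"]]
    new_rows = pd.DataFrame(
        {
            "child_id": elig["child_id"].to_numpy(),
            "recall_id": elig["recall_id"].to_numpy(),
            "raw_occasion": CANONICAL_RAW_LABEL[occasion_group],
            "occasion_group": occasion_group,
            "category": PUREE_NO_ADDED_SUGAR,
            "amount_g": elig["grams_added"].to_numpy(),
            "food_code": SIM_FOOD_CODE,
        }
    )
    for col, value in standard.composition_row().items():
        new_rows[col] = value
    new_rows = new_rows.reindex(columns=events.columns, fill_value="")
    start = (events.index.max() + 1) if len(events) else 0
    new_rows.index = range(start, start + len(new_rows))
    events_addition = pd.concat([events, new_rows])

    e_std = float(standard.composition[ENERGY])
    audit["energy_delta_addition_kcal"] = audit["grams_added"] / 100.0 * e_std

    # --- ISOPORTION: equal-proportions removal of replaceable items
    repl = events.loc[
        occ_mask & events["category"].isin(repl_cats) & (events["amount_g"] > 0),
        _KEYS + ["category", "amount_g", ENERGY + COMP_SUFFIX],
    ]
    cat_tot = (
        repl.groupby(_KEYS + ["category"], as_index=False)["amount_g"].sum()
        .rename(columns={"amount_g": "total_g"})
    )
    cat_tot = cat_tot.merge(
        audit[_KEYS + ["age_group", "grams_added", "serving_g"]], on=_KEYS, how="left"
    )
    cat_tot = cat_tot[cat_tot["grams_added"] > 0].copy()
    cat_tot["k"] = cat_tot.groupby(_KEYS)["category"].transform("size")
    item_serving = {
        (cat, ag): serving_table.serving(cat, ag, occasion_group)
        for cat in cat_tot["category"].unique()
        for ag in cat_tot["age_group"].unique()
    }
    cat_tot["item_serving_g"] = [
        item_serving[(c, a)] for c, a in zip(cat_tot["category"], cat_tot["age_group"])
    ]
    f = cat_tot["grams_added"] / cat_tot["serving_g"]
    if removal_mode == SERVINGS_MODE:
        target = f / cat_tot["k"] * cat_tot["item_serving_g"]
    elif removal_mode == GRAMS_MODE:
        target = cat_tot["grams_added"] / cat_tot["k"]
    else:
        raise ValidationError(f"unknown removal mode {removal_mode!r}")
    cat_tot["removed_g"] = np.minimum(cat_tot["total_g"], target)

    per_event = (
        repl.reset_index(names="_event_row")
        .merge(
            cat_tot[_KEYS + ["category", "total_g", "removed_g"]],
            on=_KEYS + ["category"],
            how="inner",
        )
        .set_index("_event_row")
    )
    per_event["event_removed_g"] = (
        per_event["amount_g"] / per_event["total_g"] * per_event["removed_g"]
    )

    events_isoportion = events_addition.copy()
    events_isoportion.loc[per_event.index, "amount_g"] = (
        events_isoportion.loc[per_event.index, "amount_g"] - per_event["event_removed_g"]
    ).clip(lower=0.0)

    removed_energy = (
        per_event["event_removed_g"] * per_event[ENERGY + COMP_SUFFIX] / 100.0
    ).groupby([per_event["child_id"], per_event["recall_id"]]).sum()
    audit_idx = audit.set_index(_KEYS).index
    audit["removed_energy_kcal"] = pd.Series(
        audit_idx.map(removed_energy).to_numpy(dtype=float, na_value=0.0), index=audit.index
    )
    audit["energy_delta_isoportion_kcal"] = (
        audit["energy_delta_addition_kcal"] - audit["removed_energy_kcal"]
    )

    wide = cat_tot.pivot_table(
        index=_KEYS, columns="category", values="removed_g", aggfunc="sum", fill_value=0.0
    )
    for cat in repl_cats:
        col = f"removed_{cat}_g"
        if cat in wide.columns:
            audit[col] = pd.Series(
                audit_idx.map(wide[cat]).to_numpy(dtype=float, na_value=0.0), index=audit.index
            )
        else:
            audit[col] = 0.0
    audit["removed_total_g"] = audit[[f"removed_{c}_g" for c in repl_cats]].sum(axis=1)
    has_repl = audit_idx.isin(cat_tot.set_index(_KEYS).index)
    audit["isoportion_performed"] = audit["eligible"] & has_repl
    audit["isoportion_skipped"] = audit["eligible"] & ~has_repl
    # skipped recalls keep the ADDITION diet; their isoportion energy delta is the addition one
    audit = audit.drop(columns=["puree_g", "serving_g", "removed_energy_kcal"])

    return OccasionScenarios(
        occasion_group=occasion_group,
        events_observed=events,
        events_addition=events_addition,
        events_isoportion=events_isoportion,
        audit=audit,
    )


__all__ = [
    "ADDITION",
    "GRAMS_MODE",
    "ISOPORTION",
    "OBSERVED",
    "OccasionScenarios",
    "SCENARIOS",
    "SERVINGS_MODE",
    "SIM_FOOD_CODE",
    "SimulationOutcome",
    "StandardNASFP",
    "allocate_removals",
    "find_replaceables",
    "is_eligible",
    "run_occasion_scenarios",
    "simulate_addition",
    "simulate_isoportion",
]
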