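"""Data model and I/O for children, 24-h recalls and food events.

A dataset is two tables joined on ``child_id``:

* ``children`` — one row per child: age, sex, survey weight and free
  sociodemographic columns.  Children under 1 year are excluded at load, and
  each child is assigned to one of five age groups (1-3, 4-6, 7-10, 11-14,
  15-17 completed years).
* ``events`` — one row per consumed food at one eating occasion of one recall,
  with the amount in grams and the food's per-100 g composition.  The ten raw
  occasion labels of the survey instrument collapse onto four occasion groups
  (breakfast, lunch, snack, dinner).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .nutrients import COMPOSITION_COLUMNS

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# occasions

BREAKFAST = "breakfast"
LUNCH = "lunch"
SNACK = "snack"
DINNER = "dinner"
OCCASION_GROUPS: list[str] = [BREAKFAST, LUNCH, SNACK, DINNER]

#: Default ten-label raw occasion set and its surjection onto the four groups.
DEFAULT_OCCASION_MAP: dict[str, str] = {
    "Before breakfast": BREAKFAST,
    "Breakfast": BREAKFAST,
    "In the morning": BREAKFAST,
    "Aperitif before lunch": LUNCH,
    "Lunch": LUNCH,
    "Snack": SNACK,
    "In the afternoon (excluding snacks)": SNACK,
    "Aperitif before dinner": DINNER,
    "Dinner": DINNER,
    "In the evening/night": DINNER,
}

#: Canonical raw label used when the simulation itself creates an event.
CANONICAL_RAW_LABEL: dict[str, str] = {
    BREAKFAST: "Breakfast",
    LUNCH: "Lunch",
    SNACK: "Snack",
    DINNER: "Dinner",
}

# ---------------------------------------------------------------------------
# age groups

AGE_GROUPS: list[str] = ["1-3", "4-6", "7-10", "11-14", "15-17"]
_AGE_BOUNDS: list[tuple[int, int, str]] = [
    (1, 3, "1-3"),
    (4, 6, "4-6"),
    (7, 10, "7-10"),
    (11, 14, "11-14"),
    (15, 17, "15-17"),
]

# ---------------------------------------------------------------------------
# food categories

PUREE_NO_ADDED_SUGAR = "fruit_puree_no_added_sugar"
PUREE_ADDED_SUGAR = "fruit_puree_added_sugar"
PUREE_CATEGORIES: tuple[str, str] = (PUREE_NO_ADDED_SUGAR, PUREE_ADDED_SUGAR)
#: Pseudo-category naming the pooled puree serving cell in the serving table.
POOLED_PUREE = "fruit_puree"

#: The seven sweetened categories eligible for iso-portion removal.
DEFAULT_REPLACEABLE_CATEGORIES: list[str] = [
    "soft_drink",
    "fruit_juice",
    "pastry",
    "biscuit",
    "dairy_dessert",
    "ice_cream",
    "chocolate_confectionery",
]

CATEGORIES: list[str] = [
    *PUREE_CATEGORIES,
    "fresh_fruit",
    *DEFAULT_REPLACEABLE_CATEGORIES,
    "other",
]


#: Fallback servings (g) for a category x age group with no observed events.
DEFAULT_SERVINGS: dict[str, float] = {
    POOLED_PUREE: 100.0,
    "soft_drink": 250.0,
    "fruit_juice": 150.0,
    "pastry": 60.0,
    "biscuit": 40.0,
    "dairy_dessert": 110.0,
    "ice_cream": 70.0,
    "chocolate_confectionery": 30.0,
}


class ValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


class ClassificationError(KeyError):
    """Raised for labels outside the configured classification sets."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CategoryConfig:
    """Occasion mapping, replaceable-category list and serving-rule knobs.

    ``serving_overrides`` maps ``(category, age_group, occasion_group)`` to a
    fixed serving in grams (the mechanism behind rules such as pinning the
    oldest group's snack serving to a cup of 100 g when the estimate is built
    on too few events).  ``default_servings`` supplies a serving for a
    category x age-group with no observed events at all.
    """

    occasion_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_OCCASION_MAP))
    replaceable_categories: list[str] = field(
        default_factory=lambda: list(DEFAULT_REPLACEABLE_CATEGORIES)
    )
    serving_overrides: dict[tuple[str, str, str], float] = field(default_factory=dict)
    default_servings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SERVINGS))
    robustness_threshold: int = 10

    def __post_init__(self) -> None:
        bad_targets = set(self.occasion_map.values()) - set(OCCASION_GROUPS)
        if bad_targets:
            raise ValidationError(f"occasion map targets outside the four groups: {sorted(bad_targets)}")
        if self.robustness_threshold < 1:
            raise ValidationError("robustness_threshold must be >= 1")
        for (cat, ag, occ), g in self.serving_overrides.items():
            if ag not in AGE_GROUPS or occ not in OCCASION_GROUPS or g <= 0:
                raise ValidationError(f"bad serving override ({cat}, {ag}, {occ}) -> {g}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryConfig":
        raw = yaml.safe_load(Path(path).read_text())
        overrides = {
            (o["category"], o["age_group"], o["occasion_group"]): float(o["serving_g"])
            for o in raw.get("serving_overrides", [])
        }
        return cls(
            occasion_map=raw.get("occasion_map", dict(DEFAULT_OCCASION_MAP)),
            replaceable_categories=raw.get(
                "replaceable_categories", list(DEFAULT_REPLACEABLE_CATEGORIES)
            ),
            serving_overrides=overrides,
            default_servings={k: float(v) for k, v in raw.get("default_servings", {}).items()},
            robustness_threshold=int(raw.get("robustness_threshold", 10)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "occasion_map": self.occasion_map,
            "replaceable_categories": self.replaceable_categories,
            "serving_overrides": [
                {"category": c, "age_group": a, "occasion_group": o, "serving_g": g}
                for (c, a, o), g in sorted(self.serving_overrides.items())
            ],
            "default_servings": self.default_servings,
            "robustness_threshold": self.robustness_threshold,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))

    @classmethod
    def default(cls) -> "CategoryConfig":
        path = resources.files("dietshift.data") / "category_config.yaml"
        with resources.as_file(path) as p:
            return cls.from_yaml(p)


# ---------------------------------------------------------------------------
# classification operations


def group_occasion(raw_label: str, occasion_map: dict[str, str] | None = None) -> str:
    """Map a raw eating-occasion label onto one of the four occasion groups."""
    mapping = DEFAULT_OCCASION_MAP if occasion_map is None else occasion_map
    try:
        return mapping[raw_label]
    except KeyError:
        raise ClassificationError(
            f"unknown eating-occasion label {raw_label!r}; configured labels: {sorted(mapping)}"
        ) from None


def assign_age_group(age_years: float) -> str:
    """Assign a child to an age group by completed years; partition of [1, 18)."""
    if age_years < 1:
        raise ValidationError(f"children under 1 year are excluded from the study (age {age_years})")
    if age_years >= 18:
        raise ValidationError(f"age {age_years} outside the child range [1, 18)")
    completed = int(age_years)  # completed years; 3.9 y is still in 1-3
    for lo, hi, label in _AGE_BOUNDS:
        if lo <= completed <= hi:
            return label
    raise AssertionError("unreachable: bounds partition [1, 18)")


def classify_consumer(events: pd.DataFrame) -> bool:
    """True iff any event of this child is fruit puree (either subcategory)
    with a strictly positive amount, over however many recalls were made."""
    if len(events) == 0:
        return False
    if events["child_id"].nunique() > 1:
        raise ValidationError("classify_consumer expects the events of a single child")
    mask = events["category"].isin(PUREE_CATEGORIES) & (events["amount_g"] > 0)
    return bool(mask.any())


def consumer_flags(children: pd.DataFrame, events: pd.DataFrame) -> pd.Series:
    """Per-child consumer flag, indexed like ``children`` (vectorised form)."""
    mask = events["category"].isin(PUREE_CATEGORIES) & (events["amount_g"] > 0)
    consumers = set(events.loc[mask, "child_id"])
    return children["child_id"].isin(consumers).rename("consumer")


# ---------------------------------------------------------------------------
# dataset container and I/O

REQUIRED_CHILD_COLUMNS = ["child_id", "age_years", "sex", "survey_weight"]
REQUIRED_EVENT_COLUMNS = ["child_id", "recall_id", "raw_occasion", "category", "amount_g"]


@dataclass
class DietDataset:
    """Validated roster + events; the unit every downstream stage consumes."""

    children: pd.DataFrame
    events: pd.DataFrame
    config: CategoryConfig
    n_excluded_under1: int = 0

    @property
    def sociodemo_columns(self) -> list[str]:
        reserved = set(REQUIRED_CHILD_COLUMNS) | {"age_group"}
        return [c for c in self.children.columns if c not in reserved]

    def recalls(self) -> pd.DataFrame:
        """One row per (child_id, recall_id) with the child's age group."""
        rec = self.events[["child_id", "recall_id"]].drop_duplicates(ignore_index=True)
        return rec.merge(
            self.children[["child_id", "age_group", "survey_weight"]], on="child_id", how="left"
        )


def dataset_from_frames(
    children: pd.DataFrame,
    events: pd.DataFrame,
    config: CategoryConfig | None = None,
) -> DietDataset:
    """Validate raw frames and assemble a :class:`DietDataset`.

    Enforces the full contract: required columns, positive weights, known
    categories and occasion labels, non-negative amounts and compositions,
    referential integrity, and the under-1 exclusion (dropped with a logged
    count, not an error).
    """
    config = config or CategoryConfig()
    children = children.copy()
    events = events.copy()

    missing = [c for c in REQUIRED_CHILD_COLUMNS if c not in children.columns]
    if missing:
        raise ValidationError(f"children table missing column(s): {missing}")
    missing = [c for c in REQUIRED_EVENT_COLUMNS + COMPOSITION_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"events table missing column(s): {missing}")

    if children["child_id"].duplicated().any():
        dup = children.loc[children["child_id"].duplicated(), "child_id"].tolist()
        raise ValidationError(f"duplicate child_id(s): {dup}")

    under1 = children["age_years"] < 1
    n_excluded = int(under1.sum())
    if n_excluded:
        logger.info("excluding %d child(ren) under 1 year", n_excluded)
        dropped_ids = set(children.loc[under1, "child_id"])
        children = children.loc[~under1].reset_index(drop=True)
        events = events.loc[~events["child_id"].isin(dropped_ids)].reset_index(drop=True)

    if (children["age_years"] >= 18).any():
        bad = children.loc[children["age_years"] >= 18, "child_id"].tolist()
        raise ValidationError(f"children at or over 18 years: {bad}")
    if (children["survey_weight"] <= 0).any():
        bad = children.loc[children["survey_weight"] <= 0, "child_id"].tolist()
        raise ValidationError(f"non-positive survey weight for child(ren): {bad}")

    children["age_group"] = children["age_years"].map(assign_age_group)

    orphan = ~events["child_id"].isin(set(children["child_id"]))
    if orphan.any():
        raise ValidationError(
            f"events referencing unknown child_id(s): rows {events.index[orphan].tolist()[:20]}"
        )
    if (events["amount_g"] < 0).any():
        raise ValidationError(
            f"negative amount_g in event rows {events.index[events['amount_g'] < 0].tolist()[:20]}"
        )
    comp = events[COMPOSITION_COLUMNS]
    if (comp.to_numpy() < 0).any():
        bad_rows = events.index[(comp < 0).any(axis=1)].tolist()[:20]
        raise ValidationError(f"negative composition values in event rows {bad_rows}")
    unknown_cat = ~events["category"].isin(CATEGORIES)
    if unknown_cat.any():
        raise ValidationError(
            f"unknown food categories: {sorted(events.loc[unknown_cat, 'category'].unique())}"
        )
    unknown_occ = ~events["raw_occasion"].isin(config.occasion_map)
    if unknown_occ.any():
        raise ClassificationError(
            f"unknown eating-occasion label(s): {sorted(events.loc[unknown_occ, 'raw_occasion'].unique())}"
        )
    events["occasion_group"] = events["raw_occasion"].map(config.occasion_map)
    if "food_code" not in events.columns:
        events["food_code"] = ""
    events["food_code"] = events["food_code"].fillna("").astype(str)

    return DietDataset(children=children, events=events, config=config, n_excluded_under1=n_excluded)


def load_dataset(
    children_file: str | Path,
    events_file: str | Path,
    category_config: str | Path | CategoryConfig | None = None,
) -> DietDataset:
    """Load and validate a dataset from ``children.csv`` + ``events.csv``."""
    if isinstance(category_config, (str, Path)):
        config = CategoryConfig.from_yaml(category_config)
    else:
        config = category_config
    children = pd.read_csv(children_file)
    events = pd.read_csv(events_file)
    return dataset_from_frames(children, events, config)


def write_dataset(dataset: DietDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ``children.csv``, ``events.csv`` and ``category_config.yaml``.

    Floats are written with shortest round-trip repr so a write/read cycle
    preserves amounts and compositions to full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "children": out / "children.csv",
        "events": out / "events.csv",
        "config": out / "category_config.yaml",
    }
    children = dataset.children.drop(columns=["age_group"], errors="ignore")
    events = dataset.events.drop(columns=["occasion_group"], errors="ignore")
    children.to_csv(paths["children"], index=False)
    events.to_csv(paths["events"], index=False)
    dataset.config.to_yaml(paths["config"])
    return paths


__all__ = [
    "AGE_GROUPS",
    "BREAKFAST",
    "CANONICAL_RAW_LABEL",
    "CATEGORIES",
    "CategoryConfig",
    "ClassificationError",
    "DEFAULT_OCCASION_MAP",
    "DEFAULT_REPLACEABLE_CATEGORIES",
    "DietDataset",
    "DINNER",
    "LUNCH",
    "OCCASION_GROUPS",
    "POOLED_PUREE",
    "PUREE_ADDED_SUGAR",
    "PUREE_CATEGORIES",
    "PUREE_NO_ADDED_SUGAR",
    "SNACK",
    "ValidationError",
    "assign_age_group",
    "classify_consumer",
    "consumer_flags",
    "dataset_from_frames",
    "group_occasion",
    "load_dataset",
    "write_dataset",
]
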