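"""Standard serving sizes as medians of observed consumption.

One "serving" of a food category for a given age group and eating occasion is
the median amount observed across consumption events in that cell.  Cells
with too few events to trust (fewer than ``robustness_threshold``, default 10)
fall back to the median of the same category x age group pooled over the other
occasions; explicit config overrides win over everything and are recorded as
such.  As a sanity anchor for fruit-puree cells: a pouch is 90 g and a cup is
100 g.

Medians are unweighted over events — survey weighting is reserved for
inference, not for portion description.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .recall_data import (
    AGE_GROUPS,
    OCCASION_GROUPS,
    POOLED_PUREE,
    PUREE_CATEGORIES,
    CategoryConfig,
    DietDataset,
    ValidationError,
)

ESTIMATED = "estimated"
OVERRIDE = "override"
FALLBACK = "fallback"


@dataclass(frozen=True)
class ServingCell:
    serving_g: float
    provenance: str  # estimated | override | fallback
    n_events: int

    def __post_init__(self) -> None:
        if self.serving_g <= 0:
            raise ValidationError(f"serving must be positive, got {self.serving_g}")


class ServingTable:
    """Mapping (category, age_group, occasion_group) -> :class:`ServingCell`."""

    def __init__(self, cells: dict[tuple[str, str, str], ServingCell]):
        self._cells = dict(cells)

    def cell(self, category: str, age_group: str, occasion_group: str) -> ServingCell:
        try:
            return self._cells[(category, age_group, occasion_group)]
        except KeyError:
            raise ValidationError(
                f"no serving configured for ({category}, {age_group}, {occasion_group})"
            ) from None

    def serving(self, category: str, age_group: str, occasion_group: str) -> float:
        return self.cell(category, age_group, occasion_group).serving_g

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._cells

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": c,
                "age_group": a,
                "occasion_group": o,
                "serving_g": cell.serving_g,
                "provenance": cell.provenance,
                "n_events": cell.n_events,
            }
            for (c, a, o), cell in self._cells.items()
        ]
        return pd.DataFrame(rows).sort_values(
            ["category", "age_group", "occasion_group"], ignore_index=True
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ServingTable":
        cells = {
            (r.category, r.age_group, r.occasion_group): ServingCell(
                float(r.serving_g), str(r.provenance), int(r.n_events)
            )
            for r in frame.itertuples(index=False)
        }
        return cls(cells)


def category_events(events: pd.DataFrame, category: str) -> pd.DataFrame:
    """Consumption events (amount > 0) of a category.

    The pooled pseudo-category :data:`POOLED_PUREE` selects both puree
    subcategories (the puree serving is estimated over all observed puree
    consumption regardless of added sugar) as well as rows already labelled
    with the pooled name, as in calibration frames.
    """
    if category == POOLED_PUREE:
        mask = events["category"].isin((*PUREE_CATEGORIES, POOLED_PUREE))
    else:
        mask = events["category"] == category
    return events.loc[mask & (events["amount_g"] > 0)]


def estimate_serving(
    events: pd.DataFrame,
    category: str,
    age_group: str,
    occasion_group: str,
    *,
    threshold: int = 10,
    default_serving: float | None = None,
) -> ServingCell:
    """Median observed amount in one cell, with the sparse-cell fallback.

    ``events`` must already carry ``age_group`` and ``occasion_group`` columns.
    Even event counts use the midpoint of the two central values.
    """
    cat_ev = category_events(events, category)
    cat_ev = cat_ev[cat_ev["age_group"] == age_group]
    in_cell = cat_ev[cat_ev["occasion_group"] == occasion_group]
    if len(in_cell) >= threshold:
        return ServingCell(float(np.median(in_cell["amount_g"])), ESTIMATED, len(in_cell))
    elsewhere = cat_ev[cat_ev["occasion_group"] != occasion_group]
    if len(elsewhere) > 0:
        return ServingCell(float(np.median(elsewhere["amount_g"])), FALLBACK, len(in_cell))
    if default_serving is not None:
        return ServingCell(float(default_serving), OVERRIDE, len(in_cell))
    raise ValidationError(
        f"no consumption events anywhere for ({category}, {age_group}) and no "
        f"configured default serving"
    )


def build_serving_table(dataset: DietDataset, config: CategoryConfig | None = None) -> ServingTable:
    """Serving table for pooled fruit puree and every replaceable category.

    Config ``serving_overrides`` are applied last (provenance ``override``);
    ``default_servings`` resolve category x age-group combinations with no
    events anywhere.  An unresolvable empty cell raises, naming the cells that
    need a configured default.
    """
    config = config or dataset.config
    events = dataset.events.merge(
        dataset.children[["child_id", "age_group"]], on="child_id", how="left"
    )
    categories = [POOLED_PUREE, *config.replaceable_categories]
    cells: dict[tuple[str, str, str], ServingCell] = {}
    unresolved: list[tuple[str, str, str]] = []
    for category in categories:
        for age_group in AGE_GROUPS:
            for occasion_group in OCCASION_GROUPS:
                key = (category, age_group, occasion_group)
                if key in config.serving_overrides:
                    cells[key] = ServingCell(config.serving_overrides[key], OVERRIDE, 0)
                    continue
                try:
                    cells[key] = estimate_serving(
                        events,
                        category,
                        age_group,
                        occasion_group,
                        threshold=config.robustness_threshold,
                        default_serving=config.default_servings.get(category),
                    )
                except ValidationError:
                    unresolved.append(key)
    if unresolved:
        raise ValidationError(
            "cells with no events and no configured default serving: "
            + ", ".join(map(str, unresolved))
        )
    return ServingTable(cells)


__all__ = [
    "ESTIMATED",
    "FALLBACK",
    "OVERRIDE",
    "ServingCell",
    "ServingTable",
    "build_serving_table",
    "category_events",
    "estimate_serving",
]
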