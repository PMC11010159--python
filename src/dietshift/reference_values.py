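"""Per-age-group nutrient reference values and adequacy semantics.

Three kinds of entry:

* ``floor`` — intake at or above the reference is adequate (the whole MAR
  panel of nutrients-to-favour, on an absolute per-day basis);
* ``ceiling`` — share at or below the reference is adequate (SFA and free
  sugars, on a percent-of-energy basis);
* ``range`` — adequate within [low, high] (total carbohydrates, percent of
  energy).

The repository ships an editable default table assembled from public
Anses/EFSA-style recommendations.  When a source recommendation spans only
part of an age group, the table builder is expected to have resolved it to
the more demanding value before the table is loaded here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .nutrients import MAR_PANEL
from .recall_data import AGE_GROUPS

FLOOR = "floor"
CEILING = "ceiling"
RANGE = "range"
DIRECTIONS = (FLOOR, CEILING, RANGE)

ABSOLUTE_PER_DAY = "absolute_per_day"
PERCENT_OF_ENERGY = "percent_of_energy"
BASES = (ABSOLUTE_PER_DAY, PERCENT_OF_ENERGY)

#: Nutrients whose adequacy is judged on a percent-of-energy basis.
PERCENT_BASIS_REQUIRED = {"sfa_g", "free_sugars_g"}


class ReferenceError(ValueError):
    """Configuration problem in the reference table."""


@dataclass(frozen=True)
class ReferenceEntry:
    nutrient: str
    age_group: str
    direction: str
    basis: str
    value: float = math.nan  # floor/ceiling threshold, in unit (or % of energy)
    low: float = math.nan  # range bounds
    high: float = math.nan
    unit: str = ""


class ReferenceTable:
    """Validated lookup of :class:`ReferenceEntry` by (nutrient, age group)."""

    def __init__(self, entries: list[ReferenceEntry]):
        self._entries: dict[tuple[str, str], ReferenceEntry] = {}
        for e in entries:
            key = (e.nutrient, e.age_group)
            if key in self._entries:
                raise ReferenceError(f"duplicate reference entry for {key}")
            if e.age_group not in AGE_GROUPS:
                raise ReferenceError(f"unknown age group {e.age_group!r} for {e.nutrient}")
            if e.direction not in DIRECTIONS:
                raise ReferenceError(f"unknown direction {e.direction!r} for {key}")
            if e.basis not in BASES:
                raise ReferenceError(f"unknown basis {e.basis!r} for {key}")
            if e.nutrient in PERCENT_BASIS_REQUIRED and e.basis != PERCENT_OF_ENERGY:
                raise ReferenceError(
                    f"{e.nutrient} must be expressed as percent_of_energy, got {e.basis}"
                )
            if e.direction == RANGE:
                if not (math.isfinite(e.low) and math.isfinite(e.high) and 0 <= e.low < e.high):
                    raise ReferenceError(f"range entry {key} needs 0 <= low < high")
            else:
                if not (math.isfinite(e.value) and e.value > 0):
                    raise ReferenceError(f"entry {key} needs a positive reference value")
            self._entries[key] = e
        self._check_mar_completeness()

    def _check_mar_completeness(self) -> None:
        missing = [
            (n, g)
            for g in AGE_GROUPS
            for n in MAR_PANEL
            if (n, g) not in self._entries or self._entries[(n, g)].direction != FLOOR
        ]
        if missing:
            raise ReferenceError(
                f"MAR panel incomplete (floor entry missing) for: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )

    def lookup(self, nutrient: str, age_group: str) -> ReferenceEntry:
        try:
            return self._entries[(nutrient, age_group)]
        except KeyError:
            raise ReferenceError(
                f"no reference entry for nutrient {nutrient!r} in age group {age_group!r}"
            ) from None

    def nutrients(self) -> list[str]:
        """All nutrients with at least one entry, MAR panel first."""
        seen = {n for n, _ in self._entries}
        return [n for n in MAR_PANEL if n in seen] + sorted(
            n for n in seen if n not in MAR_PANEL
        )

    def mar_references(self, age_group: str) -> pd.Series:
        """Floor reference values of the MAR panel for one age group."""
        return pd.Series(
            {n: self.lookup(n, age_group).value for n in MAR_PANEL}, name=age_group
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(e) for e in self._entries.values()]
        return pd.DataFrame(rows).sort_values(["nutrient", "age_group"], ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceTable":
        required = {"nutrient", "age_group", "direction", "basis"}
        missing = required - set(frame.columns)
        if missing:
            raise ReferenceError(f"reference table missing column(s): {sorted(missing)}")
        entries = []
        for row in frame.itertuples(index=False):
            entries.append(
                ReferenceEntry(
                    nutrient=row.nutrient,
                    age_group=row.age_group,
                    direction=row.direction,
                    basis=row.basis,
                    value=float(getattr(row, "value", math.nan)),
                    low=float(getattr(row, "low", math.nan)),
                    high=float(getattr(row, "high", math.nan)),
                    unit=str(getattr(row, "unit", "")),
                )
            )
        return cls(entries)


def load_reference_table(path: str | Path) -> ReferenceTable:
    """Load and validate ``references.csv``."""
    return ReferenceTable.from_frame(pd.read_csv(path))


def default_reference_table() -> ReferenceTable:
    """The reference table shipped with the package."""
    path = resources.files("dietshift.data") / "references.csv"
    with resources.as_file(path) as p:
        return load_reference_table(p)


__all__ = [
    "ABSOLUTE_PER_DAY",
    "CEILING",
    "FLOOR",
    "PERCENT_OF_ENERGY",
    "RANGE",
    "ReferenceEntry",
    "ReferenceError",
    "ReferenceTable",
    "default_reference_table",
    "load_reference_table",
]
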