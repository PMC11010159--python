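"""Intake aggregation, mean adequacy ratio, %-of-energy shares, adequacy flags.

The mean adequacy ratio (MAR) of an intake vector is

    MAR = (1 / N) * sum_n min(100, 100 * intake_n / ref_n)

over the N-nutrient panel of nutrients-to-favour, each ratio truncated at 100
so that excess in one nutrient cannot compensate for shortfall in another.
Daily intakes are the arithmetic mean over a child's own recalls (two or
three); occasion-level intakes are the mean over recalls of that occasion's
total, counting a recall without the occasion as zero.  Occasion-level MAR is
computed against the *daily* references — occasion values sit far below 100
and are only ever compared observed-vs-simulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nutrients import (
    ALL_NUTRIENTS,
    COMP_SUFFIX,
    ENERGY,
    ENERGY_FACTORS_KCAL_PER_G,
    MAR_PANEL,
)
from .recall_data import ValidationError
from .reference_values import CEILING, FLOOR, PERCENT_OF_ENERGY, ReferenceTable

_KEYS = ["child_id", "recall_id"]


def event_intakes(events: pd.DataFrame) -> pd.DataFrame:
    """Per-event consumed nutrient amounts: ``amount_g / 100 x composition``."""
    comp = events[[n + COMP_SUFFIX for n in ALL_NUTRIENTS]].to_numpy(dtype=float)
    intake = comp * (events["amount_g"].to_numpy(dtype=float)[:, None] / 100.0)
    out = pd.DataFrame(intake, columns=ALL_NUTRIENTS, index=events.index)
    return pd.concat([events[_KEYS + ["occasion_group"]], out], axis=1)


def _per_recall(intakes: pd.DataFrame, occasion_group: str | None) -> pd.DataFrame:
    if occasion_group is not None:
        intakes = intakes[intakes["occasion_group"] == occasion_group]
    return intakes.groupby(_KEYS, as_index=False)[ALL_NUTRIENTS].sum()


def mean_daily_intakes(
    events: pd.DataFrame,
    recalls: pd.DataFrame,
    occasion_group: str | None = None,
) -> pd.DataFrame:
    """Per-child mean intake vector over the child's own recalls.

    ``recalls`` is the roster of (child_id, recall_id) pairs (from
    ``DietDataset.recalls()``); recalls absent from ``events`` at the given
    occasion contribute zero, and the divisor is always the child's own recall
    count.  With ``occasion_group=None`` the whole day is aggregated.
    """
    per_recall = _per_recall(event_intakes(events), occasion_group)
    per_recall = recalls[_KEYS].merge(per_recall, on=_KEYS, how="left").fillna(0.0)
    return per_recall.groupby("child_id", as_index=False)[ALL_NUTRIENTS].mean()


def aggregate_intake(
    events: pd.DataFrame,
    recalls: pd.DataFrame,
    level: str = "daily",
    occasion_group: str | None = None,
) -> pd.DataFrame:
    """Intake records at ``level`` in {"recall", "daily"}.

    ``recall`` returns one row per (child, recall); ``daily`` averages those
    rows per child over the child's own recall count.
    """
    if level == "daily":
        return mean_daily_intakes(events, recalls, occasion_group)
    if level == "recall":
        per_recall = _per_recall(event_intakes(events), occasion_group)
        return recalls[_KEYS].merge(per_recall, on=_KEYS, how="left").fillna(0.0)
    raise ValidationError(f"unknown aggregation level {level!r}")


# ---------------------------------------------------------------------------
# MAR


def mar(intake: pd.Series, refs: ReferenceTable, age_group: str) -> float:
    """Mean adequacy ratio in [0, 100] of one intake vector."""
    ref = refs.mar_references(age_group)
    if (ref <= 0).any():
        raise ValidationError("MAR references must be strictly positive")
    ratios = np.minimum(100.0, 100.0 * intake.reindex(MAR_PANEL).to_numpy() / ref.to_numpy())
    return float(ratios.mean())


def mar_by_child(
    intakes: pd.DataFrame, age_groups: pd.Series, refs: ReferenceTable
) -> pd.Series:
    """Vectorised MAR for a per-child intake table (index-aligned result)."""
    ref_matrix = pd.DataFrame({ag: refs.mar_references(ag) for ag in age_groups.unique()}).T
    refs_arr = ref_matrix.loc[age_groups.to_numpy(), MAR_PANEL].to_numpy(dtype=float)
    ratios = np.minimum(100.0, 100.0 * intakes[MAR_PANEL].to_numpy(dtype=float) / refs_arr)
    return pd.Series(ratios.mean(axis=1), index=intakes.index, name="mar")


# ---------------------------------------------------------------------------
# percent of energy


def pct_energy(nutrient_g: float, energy_kcal: float, factor_kcal_per_g: float) -> float:
    """Share of energy from a nutrient: ``100 * g * factor / kcal``."""
    if energy_kcal <= 0:
        raise ValidationError("percent of energy undefined for non-positive energy intake")
    return 100.0 * nutrient_g * factor_kcal_per_g / energy_kcal


def pct_energy_column(intakes: pd.DataFrame, nutrient: str) -> pd.Series:
    """Vectorised %E for a nutrient column; NaN where energy is zero."""
    factor = ENERGY_FACTORS_KCAL_PER_G[nutrient]
    energy = intakes[ENERGY].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(energy > 0, 100.0 * intakes[nutrient].to_numpy() * factor / energy, np.nan)
    return pd.Series(share, index=intakes.index, name=f"{nutrient}_pct_e")


# ---------------------------------------------------------------------------
# adequacy


def adequacy_flags(
    daily: pd.DataFrame, age_groups: pd.Series, refs: ReferenceTable
) -> pd.DataFrame:
    """Per-child, per-nutrient adequacy flags on daily intakes.

    Floors: intake >= reference.  Ceilings (SFA, free sugars): %E <= ceiling.
    Ranges (carbohydrates): %E within bounds.  Boundary values count as
    adequate.  One boolean column per nutrient in the reference table.
    """
    nutrients = refs.nutrients()
    out = pd.DataFrame(index=daily.index)
    energy = daily[ENERGY].to_numpy(dtype=float)
    for nutrient in nutrients:
        flags = np.empty(len(daily), dtype=bool)
        for ag in age_groups.unique():
            entry = refs.lookup(nutrient, ag)
            mask = (age_groups == ag).to_numpy()
            if entry.basis == PERCENT_OF_ENERGY:
                factor = ENERGY_FACTORS_KCAL_PER_G[nutrient]
                with np.errstate(divide="ignore", invalid="ignore"):
                    value = np.where(
                        energy > 0, 100.0 * daily[nutrient].to_numpy() * factor / energy, np.inf
                    )
            else:
                value = daily[nutrient].to_numpy(dtype=float)
            if entry.direction == FLOOR:
                ok = value >= entry.value
            elif entry.direction == CEILING:
                ok = value <= entry.value
            else:
                ok = (value >= entry.low) & (value <= entry.high)
            flags[mask] = ok[mask]
        out[nutrient] = flags
    return out


__all__ = [
    "adequacy_flags",
    "aggregate_intake",
    "event_intakes",
    "mar",
    "mar_by_child",
    "mean_daily_intakes",
    "pct_energy",
    "pct_energy_column",
]
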