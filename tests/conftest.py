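import pandas as pd
import pytest

from dietshift.nutrients import ALL_NUTRIENTS, COMP_SUFFIX
from dietshift.portioning import ServingCell, ServingTable, build_serving_table
from dietshift.recall_data import (
    AGE_GROUPS,
    DEFAULT_OCCASION_MAP,
    OCCASION_GROUPS,
    POOLED_PUREE,
)
from dietshift.reference_values import default_reference_table
from dietshift.simulation import StandardNASFP
from dietshift.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def refs():
    return default_reference_table()


@pytest.fixture(scope="session")
def standard():
    return StandardNASFP.default()


@pytest.fixture(scope="session")
def small_dataset():
    """A 150-child synthetic survey shared by read-only tests."""
    return generate_dataset(GeneratorConfig(n_children=150), seed=42)


@pytest.fixture(scope="session")
def small_serving_table(small_dataset):
    return build_serving_table(small_dataset)


def make_events(rows, default_energy=100.0):
    """Build an events frame from terse specs.

    Each row: (child_id, recall_id, raw_occasion, category, amount_g) or the
    same plus a composition dict (per 100 g); unspecified nutrients are 0 and
    energy defaults to ``default_energy`` unless given.
    """
    records = []
    for row in rows:
        comp = {}
        if len(row) == 6:
            *row, comp = row
        child, recall, raw, cat, amount = row
        rec = {
            "child_id": child,
            "recall_id": recall,
            "raw_occasion": raw,
            "occasion_group": DEFAULT_OCCASION_MAP[raw],
            "category": cat,
            "amount_g": float(amount),
            "food_code": "",
        }
        for n in ALL_NUTRIENTS:
            rec[n + COMP_SUFFIX] = float(comp.get(n, default_energy if n == "energy_kcal" else 0.0))
        records.append(rec)
    return pd.DataFrame(records)


def manual_serving_table(
    nasfp_g=90.0,
    soft_drink=250.0,
    fruit_juice=150.0,
    pastry=60.0,
    biscuit=50.0,
    dairy_dessert=110.0,
    ice_cream=100.0,
    chocolate_confectionery=30.0,
):
    """Serving table with the same serving in every age group and occasion."""
    servings = {
        POOLED_PUREE: nasfp_g,
        "soft_drink": soft_drink,
        "fruit_juice": fruit_juice,
        "pastry": pastry,
        "biscuit": biscuit,
        "dairy_dessert": dairy_dessert,
        "ice_cream": ice_cream,
        "chocolate_confectionery": chocolate_confectionery,
    }
    cells = {
        (cat, ag, occ): ServingCell(g, "override", 0)
        for cat, g in servings.items()
        for ag in AGE_GROUPS
        for occ in OCCASION_GROUPS
    }
    return ServingTable(cells)
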