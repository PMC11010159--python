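"""Nutrient registry and vector arithmetic.

Every food composition and every intake in the package is expressed over a
single fixed panel of named nutrients: energy, the mean-adequacy-ratio (MAR)
panel of nutrients-to-favour, and the nutrients-to-limit.  Compositions are
per 100 g of food as consumed; intakes are amounts actually consumed, so the
conversion is always ``amount_g / 100 * composition``.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

ENERGY = "energy_kcal"

#: Nutrients-to-favour entering the mean adequacy ratio, in reference units.
MAR_PANEL: list[str] = [
    "proteins_g",
    "fibres_g",
    "vitamin_b1_mg",
    "vitamin_b2_mg",
    "vitamin_b6_mg",
    "vitamin_b9_ug",
    "vitamin_b12_ug",
    "vitamin_c_mg",
    "vitamin_d_ug",
    "vitamin_e_mg",
    "vitamin_a_ug",
    "calcium_mg",
    "potassium_mg",
    "iron_mg",
    "magnesium_mg",
    "zinc_mg",
    "copper_mg",
    "iodine_ug",
    "selenium_ug",
    "linoleic_acid_g",
    "alpha_linolenic_acid_g",
    "dha_g",
]

#: Nutrients-to-limit (ceiling or range semantics live in the reference table).
LIMIT_NUTRIENTS: list[str] = [
    "sfa_g",
    "free_sugars_g",
    "added_sugars_g",
    "sodium_mg",
    "carbohydrates_g",
    "total_fat_g",
]

ALL_NUTRIENTS: list[str] = [ENERGY, *MAR_PANEL, *LIMIT_NUTRIENTS]

COMP_SUFFIX = "_per100g"
COMPOSITION_COLUMNS: list[str] = [n + COMP_SUFFIX for n in ALL_NUTRIENTS]

#: Atwater-style energy factors (kcal per g) used for percent-of-energy shares.
ENERGY_FACTORS_KCAL_PER_G: dict[str, float] = {
    "sfa_g": 9.0,
    "total_fat_g": 9.0,
    "free_sugars_g": 4.0,
    "added_sugars_g": 4.0,
    "carbohydrates_g": 4.0,
}


def nutrient_vector(values: Mapping[str, float] | None = None, **kwargs: float) -> pd.Series:
    """Build a nutrient vector (pd.Series over :data:`ALL_NUTRIENTS`).

    Unspecified components are zero.  Unknown names or negative amounts raise
    ``ValueError``.  Addition and scalar scaling of the returned Series are the
    linear operations the rest of the package relies on.
    """
    amounts = dict(values or {})
    amounts.update(kwargs)
    unknown = set(amounts) - set(ALL_NUTRIENTS)
    if unknown:
        raise ValueError(f"unknown nutrient component(s): {sorted(unknown)}")
    vec = pd.Series(0.0, index=ALL_NUTRIENTS, dtype=float)
    for name, value in amounts.items():
        value = float(value)
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"nutrient {name!r} must be finite and >= 0, got {value}")
        vec[name] = value
    return vec


def validate_vector(vec: pd.Series) -> pd.Series:
    """Check that ``vec`` covers the full panel with non-negative components."""
    missing = set(ALL_NUTRIENTS) - set(vec.index)
    if missing:
        raise ValueError(f"nutrient vector missing component(s): {sorted(missing)}")
    vec = vec.reindex(ALL_NUTRIENTS).astype(float)
    if (vec < 0).any() or not np.isfinite(vec.to_numpy()).all():
        bad = vec[(vec < 0) | ~np.isfinite(vec)]
        raise ValueError(f"nutrient vector has negative/non-finite components: {list(bad.index)}")
    return vec
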