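"""Seeded generator of survey-like dietary recall datasets.

Emulates the *structure* of a national children's food-consumption survey
(INCA3-like): ~1 900 children aged 1-17 in five age groups, two or three
24-h recalls each, ten raw eating-occasion labels, survey weights, a
fruit-puree consumer prevalence that declines with age (above 60 % in the
two youngest groups, below 20 % in the oldest), and seven replaceable
sweet-food categories with realistic portion grids.  It does not emulate any
real food list or real composition values — compositions are plausible
per-100 g profiles with lognormal event-level noise.

Portion amounts are drawn on a 10 g grid symmetrically around planted cell
medians so that serving-size estimation has exact expectations.  A fibre
adequacy prevalence can be planted exactly: each child's fibre density is
rescaled so their observed daily fibre lands a fixed margin above or below
their age group's reference, according to a Bernoulli draw.

Generation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nutrients import ALL_NUTRIENTS, COMP_SUFFIX
from .recall_data import (
    AGE_GROUPS,
    BREAKFAST,
    CategoryConfig,
    DietDataset,
    DINNER,
    LUNCH,
    OCCASION_GROUPS,
    PUREE_ADDED_SUGAR,
    PUREE_NO_ADDED_SUGAR,
    SNACK,
    ValidationError,
    dataset_from_frames,
)
from .reference_values import default_reference_table

# raw labels by occasion group; first label of each list is the common one
_RAW_LABELS: dict[str, list[str]] = {
    BREAKFAST: ["Breakfast", "Before breakfast", "In the morning"],
    LUNCH: ["Lunch", "Aperitif before lunch"],
    SNACK: ["Snack", "In the afternoon (excluding snacks)"],
    DINNER: ["Dinner", "Aperitif before dinner", "In the evening/night"],
}

#: Plausible per-100 g composition means by category (not real survey values).
DEFAULT_FOOD_MEANS: dict[str, dict[str, float]] = {
    PUREE_NO_ADDED_SUGAR: dict(
        energy_kcal=55, proteins_g=0.4, fibres_g=1.8, vitamin_b1_mg=0.02, vitamin_b2_mg=0.02,
        vitamin_b6_mg=0.03, vitamin_b9_ug=4, vitamin_c_mg=4, vitamin_e_mg=0.3, vitamin_a_ug=3,
        calcium_mg=5, potassium_mg=90, iron_mg=0.2, magnesium_mg=5, zinc_mg=0.05, copper_mg=0.04,
        iodine_ug=0.5, selenium_ug=0.2, linoleic_acid_g=0.03, alpha_linolenic_acid_g=0.01,
        sodium_mg=2, carbohydrates_g=13, total_fat_g=0.2,
    ),
    PUREE_ADDED_SUGAR: dict(
        energy_kcal=80, proteins_g=0.4, fibres_g=1.6, vitamin_c_mg=3, potassium_mg=85,
        vitamin_b9_ug=3, magnesium_mg=4, copper_mg=0.03, sodium_mg=2, carbohydrates_g=19,
        free_sugars_g=8, added_sugars_g=8, total_fat_g=0.2,
    ),
    "fresh_fruit": dict(
        energy_kcal=55, proteins_g=0.5, fibres_g=2.2, vitamin_c_mg=15, vitamin_b9_ug=10,
        vitamin_e_mg=0.3, vitamin_a_ug=10, potassium_mg=180, magnesium_mg=10, copper_mg=0.05,
        linoleic_acid_g=0.05, alpha_linolenic_acid_g=0.02, carbohydrates_g=12, total_fat_g=0.2,
    ),
    "soft_drink": dict(
        energy_kcal=42, carbohydrates_g=10.5, free_sugars_g=10.5, added_sugars_g=10.5, sodium_mg=5,
    ),
    "fruit_juice": dict(
        energy_kcal=45, carbohydrates_g=10.4, free_sugars_g=10.4, vitamin_c_mg=30,
        potassium_mg=150, vitamin_b9_ug=15, magnesium_mg=8,
    ),
    "pastry": dict(
        energy_kcal=400, proteins_g=6, fibres_g=1.5, total_fat_g=22, sfa_g=10, carbohydrates_g=45,
        free_sugars_g=20, added_sugars_g=20, sodium_mg=300, calcium_mg=60, iron_mg=1.2,
        vitamin_e_mg=1.5, vitamin_b2_mg=0.1,
    ),
    "biscuit": dict(
        energy_kcal=470, proteins_g=6, fibres_g=2, total_fat_g=20, sfa_g=10, carbohydrates_g=65,
        free_sugars_g=28, added_sugars_g=28, sodium_mg=350, iron_mg=1.5, vitamin_b1_mg=0.08,
    ),
    "dairy_dessert": dict(
        energy_kcal=110, proteins_g=3.5, total_fat_g=3.5, sfa_g=2.2, carbohydrates_g=17,
        free_sugars_g=12, added_sugars_g=12, calcium_mg=110, vitamin_b2_mg=0.15,
        vitamin_b12_ug=0.3, iodine_ug=20, zinc_mg=0.4, sodium_mg=60,
    ),
    "ice_cream": dict(
        energy_kcal=200, proteins_g=3, total_fat_g=10, sfa_g=6.5, carbohydrates_g=24,
        free_sugars_g=20, added_sugars_g=20, calcium_mg=100, vitamin_b2_mg=0.12, vitamin_a_ug=80,
        sodium_mg=60,
    ),
    "chocolate_confectionery": dict(
        energy_kcal=530, proteins_g=6, fibres_g=3, total_fat_g=30, sfa_g=18, carbohydrates_g=57,
        free_sugars_g=50, added_sugars_g=50, magnesium_mg=60, iron_mg=2, copper_mg=0.4,
        potassium_mg=300, sodium_mg=20,
    ),
    "other": dict(
        energy_kcal=150, proteins_g=7, fibres_g=1.5, vitamin_b1_mg=0.1, vitamin_b2_mg=0.15,
        vitamin_b6_mg=0.15, vitamin_b9_ug=25, vitamin_b12_ug=0.5, vitamin_c_mg=8, vitamin_d_ug=0.7,
        vitamin_e_mg=1.0, vitamin_a_ug=60, calcium_mg=90, potassium_mg=250, iron_mg=1.2,
        magnesium_mg=25, zinc_mg=1.1, copper_mg=0.12, iodine_ug=15, selenium_ug=6,
        linoleic_acid_g=1.2, alpha_linolenic_acid_g=0.15, dha_g=0.02, sfa_g=2.5, free_sugars_g=2,
        added_sugars_g=2, sodium_mg=250, carbohydrates_g=17, total_fat_g=6,
    ),
}

GRID_STEP_G = 10


@dataclass
class GeneratorConfig:
    """Knobs of the survey emulator; defaults mirror the study conditions."""

    n_children: int = 1934
    age_group_probs: dict[str, float] = field(
        default_factory=lambda: {"1-3": 0.17, "4-6": 0.18, "7-10": 0.24, "11-14": 0.22, "15-17": 0.19}
    )
    p_three_recalls: float = 0.8
    weight_sigma: float = 0.5  # lognormal spread of survey weights
    #: share of children consuming fruit puree at least once, by age group
    consumer_prevalence: dict[str, float] = field(
        default_factory=lambda: {"1-3": 0.65, "4-6": 0.62, "7-10": 0.45, "11-14": 0.25, "15-17": 0.15}
    )
    #: target mean daily puree grams among consumers, by age group
    consumer_daily_puree_g: dict[str, float] = field(
        default_factory=lambda: {"1-3": 95.0, "4-6": 90.0, "7-10": 75.0, "11-14": 60.0, "15-17": 80.0}
    )
    p_puree_extra_recall: float = 0.7  # puree day probability beyond the first recall
    puree_no_added_share: float = 0.7
    #: which occasion a consumer's puree lands on (snack-heavy young children,
    #: dinner-heavy adolescents)
    puree_occasion_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "1-3": {BREAKFAST: 0.15, LUNCH: 0.15, SNACK: 0.50, DINNER: 0.20},
            "4-6": {BREAKFAST: 0.15, LUNCH: 0.15, SNACK: 0.50, DINNER: 0.20},
            "7-10": {BREAKFAST: 0.12, LUNCH: 0.23, SNACK: 0.40, DINNER: 0.25},
            "11-14": {BREAKFAST: 0.10, LUNCH: 0.30, SNACK: 0.25, DINNER: 0.35},
            "15-17": {BREAKFAST: 0.10, LUNCH: 0.30, SNACK: 0.15, DINNER: 0.45},
        }
    )
    snack_probability: dict[str, float] = field(
        default_factory=lambda: {"1-3": 0.9, "4-6": 0.9, "7-10": 0.85, "11-14": 0.6, "15-17": 0.5}
    )
    #: occurrence probability of each replaceable category by occasion
    replaceable_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "soft_drink": {LUNCH: 0.12, DINNER: 0.12, SNACK: 0.08},
            "fruit_juice": {BREAKFAST: 0.25, SNACK: 0.10},
            "pastry": {BREAKFAST: 0.10, SNACK: 0.15},
            "biscuit": {BREAKFAST: 0.15, SNACK: 0.35},
            "dairy_dessert": {LUNCH: 0.20, DINNER: 0.20},
            "ice_cream": {LUNCH: 0.05, DINNER: 0.05, SNACK: 0.05},
            "chocolate_confectionery": {BREAKFAST: 0.05, SNACK: 0.15},
        }
    )
    #: planted median portion of each replaceable category (10 g grid)
    replaceable_median_g: dict[str, float] = field(
        default_factory=lambda: {
            "soft_drink": 250.0, "fruit_juice": 150.0, "pastry": 60.0, "biscuit": 40.0,
            "dairy_dessert": 110.0, "ice_cream": 70.0, "chocolate_confectionery": 30.0,
        }
    )
    fresh_fruit_prob: float = 0.25
    composition_noise_sigma: float = 0.15
    #: planted share of children with adequate daily fibre (None disables)
    fibre_adequacy_prevalence: float | None = 0.40
    sociodemo_gradient: bool = True

    def validate(self) -> None:
        probs = (
            [self.p_three_recalls, self.p_puree_extra_recall, self.puree_no_added_share,
             self.fresh_fruit_prob]
            + list(self.age_group_probs.values())
            + list(self.consumer_prevalence.values())
            + list(self.snack_probability.values())
            + [p for d in self.replaceable_probs.values() for p in d.values()]
            + [p for d in self.puree_occasion_probs.values() for p in d.values()]
        )
        if self.fibre_adequacy_prevalence is not None:
            probs.append(self.fibre_adequacy_prevalence)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.n_children < 1:
            raise ValidationError("n_children must be >= 1")
        if self.weight_sigma <= 0 or self.composition_noise_sigma < 0:
            raise ValidationError("dispersion parameters must be positive")
        if abs(sum(self.age_group_probs.values()) - 1) > 1e-9:
            raise ValidationError("age group probabilities must sum to 1")

    def planted_puree_amount_g(self, age_group: str) -> float:
        """Grid point the per-puree-day amount is centred on, chosen so the
        realised consumer mean daily amount matches the configured target."""
        p3, q = self.p_three_recalls, self.p_puree_extra_recall
        factor = p3 * (1 + 2 * q) / 3 + (1 - p3) * (1 + q) / 2
        raw = self.consumer_daily_puree_g[age_group] / factor
        return float(round(raw / GRID_STEP_G) * GRID_STEP_G)

    def planted_serving_medians(self) -> dict[tuple[str, str, str], float]:
        """Planted median portion for every serving-table cell."""
        out: dict[tuple[str, str, str], float] = {}
        for ag in AGE_GROUPS:
            for occ in OCCASION_GROUPS:
                out[("fruit_puree", ag, occ)] = self.planted_puree_amount_g(ag)
                for cat, m in self.replaceable_median_g.items():
                    out[(cat, ag, occ)] = m
        return out


# ---------------------------------------------------------------------------
# helpers


def _grid_offsets(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric offsets on the 10 g grid (atom 0.5 at the centre)."""
    return rng.choice(
        [-2 * GRID_STEP_G, -GRID_STEP_G, 0, GRID_STEP_G, 2 * GRID_STEP_G],
        size=n,
        p=[0.1, 0.15, 0.5, 0.15, 0.1],
    )


def _grid_uniform(rng: np.random.Generator, lo: int, hi: int) -> float:
    """Uniform draw on the 10 g grid in [lo, hi]."""
    return float(rng.integers(lo // GRID_STEP_G, hi // GRID_STEP_G + 1) * GRID_STEP_G)


def generate_food_table(config: GeneratorConfig, seed: int = 0) -> pd.DataFrame:
    """Per-category per-100 g composition means (one row per category).

    Deterministic for a given config; the seed parameter is accepted for API
    symmetry with the other generators (event-level dispersion is applied at
    recall generation).
    """
    config.validate()
    rows = {}
    for cat, means in DEFAULT_FOOD_MEANS.items():
        vec = {n: 0.0 for n in ALL_NUTRIENTS}
        vec.update({k: float(v) for k, v in means.items()})
        rows[cat] = vec
    table = pd.DataFrame.from_dict(rows, orient="index")[ALL_NUTRIENTS]
    table.index.name = "category"
    return table


_SOCIO_LEVELS = {
    "spc": ["low", "intermediate", "high"],
    "income": ["low", "middle", "high"],
    "education": ["primary", "secondary", "higher"],
    "food_insecurity": ["secure", "insecure"],
}
# P(level | consumer status); consumers skew towards higher SES
_SOCIO_PROBS = {
    "spc": {True: [0.30, 0.42, 0.28], False: [0.35, 0.457, 0.193]},
    "income": {True: [0.193, 0.557, 0.25], False: [0.352, 0.468, 0.18]},
    "education": {True: [0.12, 0.645, 0.235], False: [0.25, 0.596, 0.154]},
    "food_insecurity": {True: [0.9435, 0.0565], False: [0.857, 0.143]},
}


def generate_population(
    config: GeneratorConfig, seed: int = 0, return_planted: bool = False
):
    """Child roster: ages, sexes, survey weights, sociodemographics.

    With ``return_planted=True`` also returns the planted per-child consumer
    flags (used internally so the sociodemographic gradient and the puree
    consumption are drawn consistently)."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_children
    groups = rng.choice(AGE_GROUPS, size=n, p=[config.age_group_probs[g] for g in AGE_GROUPS])
    bounds = {"1-3": (1, 4), "4-6": (4, 7), "7-10": (7, 11), "11-14": (11, 15), "15-17": (15, 18)}
    ages = np.array([rng.uniform(*bounds[g]) for g in groups]).round(1)
    ages = np.minimum(ages, 17.9)
    weights = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
    weights = weights / weights.mean()
    consumer = rng.random(n) < np.array([config.consumer_prevalence[g] for g in groups])

    socio = {}
    for var, levels in _SOCIO_LEVELS.items():
        if config.sociodemo_gradient:
            col = np.empty(n, dtype=object)
            for status in (True, False):
                mask = consumer == status
                col[mask] = rng.choice(levels, size=mask.sum(), p=_SOCIO_PROBS[var][status])
        else:
            pooled = np.mean([_SOCIO_PROBS[var][True], _SOCIO_PROBS[var][False]], axis=0)
            col = rng.choice(levels, size=n, p=pooled / pooled.sum())
        socio[var] = col

    roster = pd.DataFrame(
        {
            "child_id": [f"C{i:05d}" for i in range(n)],
            "age_years": ages,
            "sex": rng.choice(["M", "F"], size=n, p=[0.51, 0.49]),
            "survey_weight": weights,
            **socio,
        }
    )
    if return_planted:
        return roster, pd.Series(consumer, index=roster.index, name="planted_consumer")
    return roster


_OTHER_RANGES = {BREAKFAST: (150, 300), LUNCH: (300, 600), SNACK: (50, 150), DINNER: (300, 600)}


def generate_recalls(
    roster: pd.DataFrame,
    food_table: pd.DataFrame,
    config: GeneratorConfig,
    seed: int = 0,
    planted_consumers: pd.Series | None = None,
) -> pd.DataFrame:
    """Food events for every recall of every child in the roster."""
    from .recall_data import assign_age_group

    config.validate()
    rng = np.random.default_rng(seed + 1)
    if planted_consumers is None:
        ags = roster["age_years"].map(assign_age_group)
        planted_consumers = pd.Series(
            rng.random(len(roster)) < ags.map(config.consumer_prevalence).to_numpy(),
            index=roster.index,
        )

    rows: list[tuple] = []  # child_id, recall_id, raw_occasion, occ_group, category, amount

    def raw_label(occ: str) -> str:
        labels = _RAW_LABELS[occ]
        if len(labels) == 2:
            return labels[rng.choice([0, 1], p=[0.8, 0.2])]
        return labels[rng.choice([0, 1, 2], p=[0.8, 0.1, 0.1])]

    for child, age, is_consumer in zip(
        roster["child_id"], roster["age_years"], planted_consumers
    ):
        ag = assign_age_group(age)
        n_recalls = 3 if rng.random() < config.p_three_recalls else 2
        puree_center = config.planted_puree_amount_g(ag)
        occ_probs = config.puree_occasion_probs[ag]
        for r in range(n_recalls):
            recall_id = f"{child}-R{r + 1}"
            occasions = [BREAKFAST, LUNCH, DINNER]
            if rng.random() < config.snack_probability[ag]:
                occasions.insert(2, SNACK)
            for occ in occasions:
                lo, hi = _OTHER_RANGES[occ]
                rows.append((child, recall_id, raw_label(occ), occ, "other", _grid_uniform(rng, lo, hi)))
                if occ != BREAKFAST and rng.random() < config.fresh_fruit_prob:
                    rows.append((child, recall_id, raw_label(occ), occ, "fresh_fruit", _grid_uniform(rng, 80, 150)))
                for cat, occ_p in config.replaceable_probs.items():
                    p = occ_p.get(occ, 0.0)
                    if p and rng.random() < p:
                        amount = config.replaceable_median_g[cat] + float(_grid_offsets(rng, 1)[0])
                        rows.append((child, recall_id, raw_label(occ), occ, cat, amount))
            if is_consumer and (r == 0 or rng.random() < config.p_puree_extra_recall):
                occ = rng.choice(OCCASION_GROUPS, p=[occ_probs[o] for o in OCCASION_GROUPS])
                cat = (
                    PUREE_NO_ADDED_SUGAR
                    if rng.random() < config.puree_no_added_share
                    else PUREE_ADDED_SUGAR
                )
                amount = puree_center + float(_grid_offsets(rng, 1)[0])
                rows.append((child, recall_id, raw_label(occ), occ, cat, amount))

    events = pd.DataFrame(
        rows, columns=["child_id", "recall_id", "raw_occasion", "occasion_group", "category", "amount_g"]
    )

    # per-event compositions: category means with multiplicative lognormal noise
    comp_means = food_table.loc[events["category"], ALL_NUTRIENTS].to_numpy(dtype=float)
    noise = rng.lognormal(
        mean=0.0, sigma=config.composition_noise_sigma, size=comp_means.shape
    )
    comp = comp_means * noise
    comp_frame = pd.DataFrame(
        comp, columns=[n + COMP_SUFFIX for n in ALL_NUTRIENTS], index=events.index
    )
    events = pd.concat([events.drop(columns=["occasion_group"]), comp_frame], axis=1)

    if config.fibre_adequacy_prevalence is not None:
        events = _plant_fibre_adequacy(events, roster, config, rng)
    return events


def _plant_fibre_adequacy(
    events: pd.DataFrame, roster: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Rescale each child's fibre density so daily fibre lands above or below
    the age reference per a Bernoulli draw with the configured prevalence.

    The landing ratio is graded — uniform on [1.02, 1.6] for adequate
    children, [0.50, 0.995] for inadequate ones — so the observed prevalence
    equals the planted draw exactly (nobody sits inside the dead zone around
    1.0) while children near the floor can still be tipped over by a
    fibre-bearing addition, as in real diets."""
    from .recall_data import assign_age_group

    refs = default_reference_table()
    col = "fibres_g" + COMP_SUFFIX
    fibre_intake = events["amount_g"] / 100.0 * events[col]
    per_recall = fibre_intake.groupby([events["child_id"], events["recall_id"]]).sum()
    daily = per_recall.groupby("child_id").mean()

    adequate = rng.random(len(roster)) < config.fibre_adequacy_prevalence
    ratios = np.where(
        adequate,
        rng.uniform(1.02, 1.60, len(roster)),
        rng.uniform(0.50, 0.995, len(roster)),
    )
    scale = {}
    for child, age, ratio in zip(roster["child_id"], roster["age_years"], ratios):
        ref = refs.lookup("fibres_g", assign_age_group(age)).value
        target = ref * ratio
        current = daily.get(child, 0.0)
        scale[child] = target / current if current > 0 else 1.0
    events = events.copy()
    events[col] = events[col] * events["child_id"].map(scale)
    return events


def generate_dataset(
    config: GeneratorConfig | None = None, seed: int = 0
) -> DietDataset:
    """Full synthetic survey: roster + events, validated like any loaded data."""
    config = config or GeneratorConfig()
    config.validate()
    roster, planted = generate_population(config, seed, return_planted=True)
    food_table = generate_food_table(config, seed)
    events = generate_recalls(roster, food_table, config, seed, planted_consumers=planted)
    return dataset_from_frames(roster, events, CategoryConfig())


def generate_portion_calibration_events(
    planted_medians: dict[tuple[str, str, str], float],
    n_per_cell: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Events whose per-cell median equals the planted value *exactly*.

    Amounts are built as symmetric pairs (m - d, m + d) on the 10 g grid plus
    the centre for odd counts, then shuffled; any sample size therefore has
    the planted median.  Returns a calibration frame with ``category``,
    ``age_group``, ``occasion_group`` and ``amount_g`` columns, ready for
    :func:`dietshift.portioning.estimate_serving`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (cat, ag, occ), m in planted_medians.items():
        amounts = []
        n_pairs, odd = divmod(n_per_cell, 2)
        for _ in range(n_pairs):
            d = float(rng.choice([GRID_STEP_G, 2 * GRID_STEP_G]))
            amounts.extend([m - d, m + d])
        if odd:
            amounts.append(m)
        rng.shuffle(amounts)
        rows.extend((cat, ag, occ, a) for a in amounts)
    return pd.DataFrame(rows, columns=["category", "age_group", "occasion_group", "amount_g"])


__all__ = [
    "DEFAULT_FOOD_MEANS",
    "GRID_STEP_G",
    "GeneratorConfig",
    "generate_dataset",
    "generate_food_table",
    "generate_population",
    "generate_portion_calibration_events",
    "generate_recalls",
]
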