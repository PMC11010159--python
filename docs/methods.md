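# Methods

This note documents the model implemented by `dietshift`, its assumptions,
the defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Data model and classification

A dataset is a child roster (age, sex, survey weight, sociodemographics)
plus a food-event table (child, recall, raw eating-occasion label, food
category, grams consumed, per-100 g composition). Intake of any nutrient is
always `amount_g / 100 × composition`; total energy always comes from the
composition's energy field and is never re-derived from macronutrients.

* **Under-1 exclusion.** Children under 1 year are dropped at load with a
  logged count; their events are dropped with them.
* **Age groups.** 1–3, 4–6, 7–10, 11–14, 15–17 completed years, a partition
  of [1, 18). A fractional age maps by its completed years (3.9 y → 1–3).
  A child's age at the first recall is used for all their recalls; the data
  carry no per-recall dates, so birthdays between recalls are ignored.
* **Occasion grouping.** The ten raw labels of the survey instrument map
  surjectively onto breakfast / lunch / snack / dinner. The mapping ships as
  config (`data/category_config.yaml`) so other surveys can substitute their
  own label set.
* **Consumers.** A child is a fruit-puree consumer if any event over their
  2–3 recalls is fruit puree (with or without added sugars) with a strictly
  positive amount — amount and frequency otherwise do not matter.
* **Recall counts.** Children with only two recalls are retained; every
  per-child daily mean divides by that child's own recall count.

## Reference values

Adequacy semantics live in a per-(nutrient × age group) table with three
entry types: floors (the 22-nutrient MAR panel, absolute per day), ceilings
(SFA at 12 %E, free sugars at 10 %E), and a range (carbohydrates, 40–55 %E).
The shipped `data/references.csv` is an editable default assembled from
public French/European-style recommendations; analyses that need a specific
national table can load their own CSV. When a source recommendation spans
only part of an age group, the table builder must resolve it to the more
demanding value before loading. The MAR panel is validated complete for
every age group at load, so the MAR is always computable.

The panel has 22 nutrients: proteins, fibres, vitamins B1/B2/B6/B9/B12, C,
D, E, A, calcium, potassium, iron, magnesium, zinc, copper, iodine,
selenium, linoleic acid, α-linolenic acid and DHA. The MAR denominator is
the configured panel size, never a hard-coded constant.

## Serving sizes

A standard serving of a category for (age group × occasion) is the
unweighted median of observed consumption events in that cell (even counts:
midpoint of the two central values). Survey weights are deliberately not
used here — weighting is reserved for inference; portion description is a
property of the consumption events themselves.

Cells with fewer than 10 events (configurable) are considered unrobust and
fall back to the median of the same category × age group pooled over the
other occasions; the provenance (`estimated` / `fallback` / `override`) and
event count are recorded per cell. Explicit config overrides win over
everything — this is the general mechanism for rules like pinning an
adolescent snack serving to a cup of 100 g when the cell estimate rests on a
handful of recalls. The fruit-puree serving pools both puree subcategories,
since what is being measured is the portion of puree people eat, not its
labelling. Sanity anchor for puree cells: a pouch is 90 g, a cup 100 g.

## Scenarios

Both scenarios act per recall × per occasion, each occasion simulated
successively on a fresh copy of the observed data (never chained), so a
simulated day contains exactly one modified occasion. Recalls are treated
as independent. Eligibility: the occasion must contain *strictly less* than
one puree serving (both subcategories counted).

* **ADDITION** appends one NASFP event of `serving − current puree grams`
  with the standard composition (shipped in `data/standard_nasfp.csv`: an
  apple-puree-like profile, 55 kcal/100 g, zero free and added sugars, SFA
  0). Added events carry the reserved food code `SIM-NASFP` so audits and
  round-trips can tell simulated events from observed ones.
* **ISOPORTION SUBSTITUTION** runs ADDITION, then removes replaceable items
  at that occasion. Removal is denominated in *servings*: with fraction
  `f = grams added / puree serving ∈ (0, 1]` and `k` replaceable items
  present, item *i*'s removal target is `(f/k) × serving_i`. The rationale:
  replaceable-item servings are estimated exactly like the puree serving,
  which only makes sense if they denominate the removal. A grams-denominated
  variant (total removal target = grams added, split equally) is available
  via `removal_mode="grams"` for sensitivity analyses.
* Multiple events of one replaceable category at an occasion are merged
  into a single *item* for the f/k split; the removal is then spread
  pro-rata over the category's events. "Item" means the food, not the row.
* If an item's amount is below its target it is removed entirely, with no
  redistribution to other items and no change to the puree added — the
  strict reading of the rule, so simulated occasions can end up lighter (or
  heavier) than iso-portion in edge cases.
* An eligible recall with no replaceable item keeps its ADDITION diet in
  the ISOPORTION scenario and is flagged `isoportion_skipped`; this is why
  population-level ISOPORTION energy can sit above observed at occasions
  where replaceables are rare.

The engine exists twice by design: per-recall functions
(`simulate_addition`, `simulate_isoportion`) that are easy to read and to
oracle-test, and a vectorised `run_occasion_scenarios` used by the pipeline;
a test pins their equivalence on sampled recalls.

## Metrics

* Daily intake: arithmetic mean of per-recall totals over the child's own
  recalls. Occasion intake: the same with the sum restricted to the
  occasion, a recall without that occasion contributing zero.
* MAR: mean of `min(100, 100·intake/ref)` over the panel. Occasion-level
  MAR divides by the *daily* references: occasion MARs sit far below 100 and
  are only used relatively (observed vs simulated), so the choice of
  denominator cancels; it is stated here because the alternative
  (occasion-prorated references) would scale but not reorder the comparison.
* %E shares use 4 kcal/g for sugars and carbohydrates and 9 kcal/g for fat
  and SFA. Per-child occasion shares are the ratio of the child's mean
  occasion nutrient energy to mean occasion energy; a child with zero
  observed energy at an occasion has an undefined share and is excluded
  pairwise from that %E comparison (the count is reported as `n`).
* Adequacy: floors are met at `intake ≥ ref`, ceilings at `share ≤ ref`,
  ranges within bounds — boundary values count as adequate. The strict
  variants differ only on measure-zero inputs; one convention is fixed for
  determinism.

## Survey-weighted inference

Weights correct unequal sampling probability and non-response. Inference
uses Kish's effective sample size `ESS = (Σw)²/Σw²`:

* Paired shifts: weighted one-sample t on per-child deltas against zero,
  variance from normalized weights scaled by ESS, df = ESS − 1. All-zero
  deltas are reported as a no-shift (p = 1), a non-zero constant shift as
  degenerate-significant (p = 0) — degenerate inputs never raise.
* Prevalence shifts: Pearson chi-square on the weighted 2×2 table rescaled
  to nominal sample sizes, divided by the Kish design effect (a first-order
  Rao–Scott-style correction). Zero expected cells short-circuit to a
  flagged p = 1.
* With all weights equal, both reduce *exactly* to the classical unweighted
  tests — the verifiable contract, since the exact design-based formulas of
  any given survey system are not reproducible without its design variables.
  Replicating every child k times at weight/k leaves every weighted
  *estimate* unchanged; test statistics are not invariant to replication
  (replicates are, by construction, treated as independent observations).
* No multiple-testing correction; every comparison is read at a flat 5 %
  level. This mirrors the descriptive, comparison-rich reporting style of
  dietary-survey analyses and is a deliberate non-adjustment.
* Variance estimation by replicate weights or bootstrap is out of scope:
  the design variables it would need are survey-specific and restricted.

## Synthetic surveys

The generator emulates the *structure* of a national children's survey:
1 934 children by default across five age groups (probabilities 0.17 / 0.18
/ 0.24 / 0.22 / 0.19), three recalls with probability 0.8 else two,
lognormal weights (σ = 0.5, mean-normalised), ten raw occasion labels,
consumer prevalence by age group 65 / 62 / 45 / 25 / 15 %, consumers' mean
daily puree targets 95 / 90 / 75 / 60 / 80 g/d (snack-heavy in young
children, dinner-heavy in adolescents), seven replaceable categories with
occasion-specific occurrence probabilities and planted median portions
(soft drink 250 g, juice 150 g, pastry 60 g, biscuit 40 g, dairy dessert
110 g, ice cream 70 g, chocolate 30 g), and an optional sociodemographic
gradient (consumers skew towards higher education/income; default on).

Choices made for testability:

* **Portion grids.** All amounts live on a 10 g grid, drawn symmetrically
  around planted cell medians, so serving-size recovery has exact
  expectations; a calibration generator builds cells whose sample median
  equals the planted value for *any* sample size by pairing offsets.
* **Fibre planting.** Each child's fibre density is rescaled so their
  observed daily fibre lands at a drawn ratio of their age reference —
  uniform on [1.02, 1.60] if a Bernoulli draw (default p = 0.40) marks them
  adequate, [0.50, 0.995] otherwise. The observed adequacy prevalence
  therefore equals the planted draw exactly, while near-floor children can
  still be tipped over by the puree's fibre.
* **Compositions** are plausible per-100 g category profiles with
  multiplicative lognormal event noise (σ = 0.15); the no-added-sugar puree
  has exactly zero free and added sugars by construction.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: a real food list or real composition values,
correlation between foods within a meal, day-of-week and seasonal structure,
intra-child correlation of portion sizes across recalls, measurement error
of the recall instrument, and any design clustering behind the weights.
Tests on synthetic data validate the *machinery* (classification, medians,
scenario arithmetic, weighting, determinism), not substantive nutritional
conclusions.

## Numerical and reproducibility notes

* Generation, simulation and reporting are pure functions of
  (config, seed); the run manifest is written next to the outputs and
  re-running it reproduces every CSV byte-for-byte (fixed float format,
  deterministic orderings).
* Dataset CSVs are written with shortest round-trip float repr, so a
  write/read cycle preserves amounts and compositions exactly.
* Default problem sizes: unit tests run on 60–400-child surveys; the
  invariant suite sweeps ~10 800 recalls; parameter recovery runs at the
  survey's own n = 1934. These sizes keep the full suite under half a
  minute while leaving binomial recovery intervals tight.
* Known limitations: simulated days can contain more than one puree serving
  across occasions (occasions are simulated independently, and daily
  adequacy is evaluated on such days); fresh-fruit consumption does not
  gate eligibility; added-sugar puree already present is topped up, not
  replaced. All three mirror the simulation design rather than oversights.
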