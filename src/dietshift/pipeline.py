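"""End-to-end study orchestration and report tables.

``run_study`` takes a :class:`RunManifest` (either generator settings or
paths to survey files), builds the serving table, runs both scenarios at
every requested eating occasion — each occasion simulated successively on a
fresh copy of the observed data, never chained — and emits:

* ``occasion_comparison.csv`` — per occasion x scenario x age stratum:
  weighted mean energy, MAR, SFA %E and free-sugars %E observed vs simulated,
  with weighted paired tests on the per-child shifts;
* ``adequacy_comparison.csv`` — per occasion x scenario x nutrient: weighted
  prevalence of daily adequacy before/after, the delta in percentage points,
  and the design-weighted chi-square test;
* ``consumers_sociodemo.csv`` / ``consumers_nutrients.csv`` — fruit-puree
  consumer vs non-consumer profile;
* ``eligibility_summary.csv`` — the share of recalls entering each
  simulation;
* ``servings.csv``, per-scenario outcome audits, and ``manifest.json``.

Everything is computed before anything is written, so a failing stage leaves
no partial output, and all CSVs are written with a fixed float format so a
re-run from the same manifest is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .metrics import adequacy_flags, mar_by_child, mean_daily_intakes, pct_energy_column
from .portioning import build_serving_table
from .recall_data import (
    AGE_GROUPS,
    OCCASION_GROUPS,
    DietDataset,
    load_dataset,
)
from .reference_values import ReferenceTable, default_reference_table, load_reference_table
from .simulation import (
    ADDITION,
    ISOPORTION,
    SCENARIOS,
    SERVINGS_MODE,
    StandardNASFP,
    run_occasion_scenarios,
)
from .survey_stats import compare_consumer_groups, paired_shift_test, prevalence_test
from .synthetic import GeneratorConfig, generate_dataset

_FLOAT_FORMAT = "%.10g"

_METRICS = ["energy_kcal", "mar", "sfa_pct_e", "free_sugars_pct_e"]


@dataclass
class RunManifest:
    """Everything needed to reproduce a study run byte-for-byte."""

    out_dir: str
    seed: int = 0
    generator: GeneratorConfig | None = None
    children_file: str | None = None
    events_file: str | None = None
    category_config_file: str | None = None
    reference_file: str | None = None
    standard_nasfp_file: str | None = None
    occasions: list[str] = field(default_factory=lambda: list(OCCASION_GROUPS))
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIOS))
    removal_mode: str = SERVINGS_MODE
    by_age_group: bool = True
    version: str = __version__

    def to_json(self) -> str:
        raw = dataclasses.asdict(self)
        return json.dumps(raw, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        raw = json.loads(text)
        if raw.get("generator") is not None:
            raw["generator"] = GeneratorConfig(**raw["generator"])
        raw.pop("version", None)
        return cls(**raw)


@dataclass
class StudyReport:
    manifest: RunManifest
    occasion_comparison: pd.DataFrame
    adequacy_comparison: pd.DataFrame
    consumers_sociodemo: pd.DataFrame
    consumers_nutrients: pd.DataFrame
    eligibility_summary: pd.DataFrame
    servings: pd.DataFrame
    audits: dict[str, pd.DataFrame]  # per occasion
    occasion_child_metrics: dict[tuple[str, str], pd.DataFrame]  # (occasion, scenario) incl. OBSERVED


def _load_study_inputs(manifest: RunManifest) -> tuple[DietDataset, ReferenceTable, StandardNASFP]:
    if manifest.generator is not None:
        dataset = generate_dataset(manifest.generator, manifest.seed)
    elif manifest.children_file and manifest.events_file:
        dataset = load_dataset(
            manifest.children_file, manifest.events_file, manifest.category_config_file
        )
    else:
        raise ValueError("manifest needs either a generator config or data file paths")
    refs = (
        load_reference_table(manifest.reference_file)
        if manifest.reference_file
        else default_reference_table()
    )
    standard = (
        StandardNASFP.from_csv(manifest.standard_nasfp_file)
        if manifest.standard_nasfp_file
        else StandardNASFP.default()
    )
    return dataset, refs, standard


def child_occasion_metrics(
    events: pd.DataFrame,
    recalls: pd.DataFrame,
    children: pd.DataFrame,
    refs: ReferenceTable,
    occasion_group: str,
) -> pd.DataFrame:
    """Per-child occasion-level energy, MAR and %E shares (means over recalls).

    %E shares are the ratio of the child's mean occasion nutrient energy to
    mean occasion energy; children with zero energy at the occasion get NaN
    shares and are excluded from paired %E comparisons downstream.
    """
    intakes = mean_daily_intakes(events, recalls, occasion_group)
    intakes = intakes.merge(
        children[["child_id", "age_group", "survey_weight"]], on="child_id", how="left"
    )
    intakes["mar"] = mar_by_child(intakes, intakes["age_group"], refs)
    intakes["sfa_pct_e"] = pct_energy_column(intakes, "sfa_g")
    intakes["free_sugars_pct_e"] = pct_energy_column(intakes, "free_sugars_g")
    return intakes


def _occasion_comparison_rows(
    occ: str,
    scenario: str,
    obs: pd.DataFrame,
    sim: pd.DataFrame,
    by_age_group: bool,
) -> list[dict]:
    merged = obs.merge(sim, on="child_id", suffixes=("_obs", "_sim"))
    strata = [("all", merged)]
    if by_age_group:
        strata += [
            (ag, merged[merged["age_group_obs"] == ag]) for ag in AGE_GROUPS
        ]
    rows = []
    for label, frame in strata:
        for metric in _METRICS:
            b, a = frame[f"{metric}_obs"], frame[f"{metric}_sim"]
            ok = b.notna() & a.notna()
            row = dict(
                occasion_group=occ, scenario=scenario, age_group=label, metric=metric,
                n=int(ok.sum()),
            )
            if ok.sum() >= 2:
                w = frame.loc[ok, "survey_weight_obs"]
                from .survey_stats import weighted_mean

                test = paired_shift_test(b[ok], a[ok], w)
                row.update(
                    mean_observed=weighted_mean(b[ok], w),
                    mean_simulated=weighted_mean(a[ok], w),
                    delta=test.estimate,
                    statistic=test.statistic,
                    pvalue=test.pvalue,
                    note=test.note,
                )
            else:
                row.update(
                    mean_observed=math.nan, mean_simulated=math.nan, delta=math.nan,
                    statistic=math.nan, pvalue=math.nan, note="not-estimable",
                )
            rows.append(row)
    return rows


def run_study(manifest: RunManifest, write: bool = True) -> StudyReport:
    """Run the whole observed-vs-simulated study described by ``manifest``."""
    dataset, refs, standard = _load_study_inputs(manifest)
    serving_table = build_serving_table(dataset)
    recalls = dataset.recalls()
    children = dataset.children

    daily_obs = mean_daily_intakes(dataset.events, recalls)
    daily_obs = daily_obs.merge(
        children[["child_id", "age_group", "survey_weight"]], on="child_id"
    )
    flags_obs = adequacy_flags(daily_obs, daily_obs["age_group"], refs)
    weights = daily_obs["survey_weight"].to_numpy()

    occ_rows: list[dict] = []
    adeq_rows: list[dict] = []
    elig_rows: list[dict] = []
    audits: dict[str, pd.DataFrame] = {}
    child_metrics: dict[tuple[str, str], pd.DataFrame] = {}

    from .simulation import OBSERVED
    from .survey_stats import weighted_prevalence

    for occ in manifest.occasions:
        scen = run_occasion_scenarios(
            dataset, serving_table, standard, occ, manifest.removal_mode
        )
        audits[occ] = scen.audit
        obs_metrics = child_occasion_metrics(dataset.events, recalls, children, refs, occ)
        child_metrics[(occ, OBSERVED)] = obs_metrics

        scenario_events = {ADDITION: scen.events_addition, ISOPORTION: scen.events_isoportion}
        for scenario in manifest.scenarios:
            sim_events = scenario_events[scenario]
            sim_metrics = child_occasion_metrics(sim_events, recalls, children, refs, occ)
            child_metrics[(occ, scenario)] = sim_metrics
            occ_rows.extend(
                _occasion_comparison_rows(occ, scenario, obs_metrics, sim_metrics,
                                          manifest.by_age_group)
            )

            daily_sim = mean_daily_intakes(sim_events, recalls)
            daily_sim = daily_sim.merge(
                children[["child_id", "age_group", "survey_weight"]], on="child_id"
            )
            flags_sim = adequacy_flags(daily_sim, daily_sim["age_group"], refs)
            for nutrient in flags_obs.columns:
                before = flags_obs[nutrient].to_numpy()
                after = flags_sim[nutrient].to_numpy()
                test = prevalence_test(before, after, weights)
                prev_b = weighted_prevalence(before, weights)
                prev_a = weighted_prevalence(after, weights)
                adeq_rows.append(
                    dict(
                        occasion_group=occ, scenario=scenario, nutrient=nutrient,
                        prev_observed_pct=prev_b, prev_simulated_pct=prev_a,
                        delta_points=prev_a - prev_b, statistic=test.statistic,
                        pvalue=test.pvalue, note=test.note,
                    )
                )

        audit_ag = scen.audit
        for ag in ["all", *AGE_GROUPS]:
            sub = audit_ag if ag == "all" else audit_ag[audit_ag["age_group"] == ag]
            n = len(sub)
            elig_rows.append(
                dict(
                    occasion_group=occ, age_group=ag, n_recalls=n,
                    pct_eligible=100.0 * sub["eligible"].mean() if n else math.nan,
                    pct_isoportion_performed=100.0 * sub["isoportion_performed"].mean() if n else math.nan,
                    pct_isoportion_skipped=100.0 * sub["isoportion_skipped"].mean() if n else math.nan,
                )
            )

    profile = compare_consumer_groups(dataset, refs)

    report = StudyReport(
        manifest=manifest,
        occasion_comparison=pd.DataFrame(occ_rows),
        adequacy_comparison=pd.DataFrame(adeq_rows),
        consumers_sociodemo=profile.sociodemo,
        consumers_nutrients=profile.nutrients,
        eligibility_summary=pd.DataFrame(elig_rows),
        servings=serving_table.to_frame(),
        audits=audits,
        occasion_child_metrics=child_metrics,
    )
    if write:
        _write_report(report)
    return report


def _write_report(report: StudyReport) -> None:
    out = Path(report.manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "occasion_comparison.csv": report.occasion_comparison,
        "adequacy_comparison.csv": report.adequacy_comparison,
        "consumers_sociodemo.csv": report.consumers_sociodemo,
        "consumers_nutrients.csv": report.consumers_nutrients,
        "eligibility_summary.csv": report.eligibility_summary,
        "servings.csv": report.servings,
        "headline_deltas.csv": summarize_deltas(report),
    }
    for occ, audit in report.audits.items():
        tables[f"outcomes_{occ}.csv"] = audit
    for name, frame in tables.items():
        frame.to_csv(out / name, index=False, float_format=_FLOAT_FORMAT)
    (out / "manifest.json").write_text(report.manifest.to_json())


def summarize_deltas(report: StudyReport) -> pd.DataFrame:
    """Headline table: per occasion x scenario, the all-ages deltas in energy,
    MAR and %E alongside per-nutrient adequacy-prevalence deltas in points,
    with a ``significant`` marker at the 5 % level."""
    occ = report.occasion_comparison
    occ_all = occ[occ["age_group"] == "all"]
    wide = occ_all.pivot_table(
        index=["occasion_group", "scenario"], columns="metric", values="delta"
    ).rename(columns=lambda m: f"delta_{m}")
    adeq = report.adequacy_comparison.copy()
    adeq["significant"] = adeq["pvalue"] < 0.05
    merged = adeq.merge(wide.reset_index(), on=["occasion_group", "scenario"], how="left")
    cols = [
        "occasion_group", "scenario", "nutrient", "prev_observed_pct", "prev_simulated_pct",
        "delta_points", "significant",
        *[f"delta_{m}" for m in _METRICS if f"delta_{m}" in merged.columns],
    ]
    return merged[cols].sort_values(
        ["occasion_group", "scenario", "nutrient"], ignore_index=True
    )


__all__ = ["RunManifest", "StudyReport", "child_occasion_metrics", "run_study", "summarize_deltas"]
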