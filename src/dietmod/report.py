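"""End-to-end pipeline orchestration and report-table generation.

``run_pipeline`` executes: (simulate or load) -> validate -> per-child
intakes -> energy-outlier exclusion -> usual-intake adjustment ->
baseline adequacy -> each scenario -> before/after comparisons ->
variance-ratio sensitivity sweep, and writes CSV tables, prevalence
figures and a run manifest (config hash, seed, stage counts).

Report tables round the way survey reports print: intakes to one
decimal, prevalences to whole percent, servings to one decimal; all
underlying CSVs keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import adequacy_stats, intake_engine, scenario_engine, usual_intake
from .errors import DietmodError
from .nutrients import DAIRY_TAGS, NUTRIENTS
from .reference_data import ServingRule, load_milks, load_references
from .synthetic_survey import PopulationSpec, generate_survey

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)


def _default_scenarios() -> list[scenario_engine.ScenarioSpec]:
    S = scenario_engine.ScenarioSpec
    return [
        S(kind="substitution", milk="fortified"),
        S(kind="addition", milk="fortified", cap_servings=2.0),
        S(kind="addition", milk="buffalo", cap_servings=2.0),
        S(kind="addition", milk="fortified", cap_servings=1.0),
        S(kind="addition", milk="buffalo", cap_servings=1.0),
    ]


class RunConfig(BaseModel):
    """Everything needed to reproduce one pipeline run."""

    recall_path: str | None = None
    foods_path: str | None = None
    references_path: str | None = None
    milks_path: str | None = None
    outdir: str = "dietmod_out"
    seed: int = 0
    population: PopulationSpec = Field(default_factory=PopulationSpec)
    usual: usual_intake.UsualIntakeConfig = Field(
        default_factory=usual_intake.UsualIntakeConfig)
    scenarios: list[scenario_engine.ScenarioSpec] = Field(
        default_factory=_default_scenarios)
    sweep_ratios: list[float] = Field(
        default_factory=lambda: [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    sweep_nutrients: list[str] = Field(
        default_factory=lambda: ["calcium_mg", "vitamin_c_mg", "iron_mg"])
    make_plots: bool = True


def validate_inputs(recall: pd.DataFrame, foods: pd.DataFrame) -> list[dict]:
    """Schema, referential-integrity and range checks; returns issue list.

    Each issue is ``{"severity": "hard"|"warn", "message": ...}``; hard
    issues should abort the run.
    """
    issues: list[dict] = []
    for col in intake_engine.RECALL_COLUMNS:
        if col not in recall.columns:
            issues.append({"severity": "hard",
                           "message": f"recall missing column '{col}'"})
    need = {"food_code", *NUTRIENTS, "retinol_fraction", "folic_acid_fraction"}
    for col in sorted(need - set(foods.columns)):
        issues.append({"severity": "hard",
                       "message": f"foods missing column '{col}'"})
    if any(i["severity"] == "hard" for i in issues):
        return issues
    unknown = sorted(set(recall["food_code"]) - set(foods["food_code"]))
    for code in unknown:
        issues.append({"severity": "hard",
                       "message": f"unknown food code '{code}' in recall"})
    if (recall["grams"] < 0).any():
        issues.append({"severity": "hard", "message": "negative gram amounts"})
    ages = recall["age"]
    if ((ages < 5) | (ages > 9)).any():
        bad = sorted(ages[(ages < 5) | (ages > 9)].unique().tolist())
        issues.append({"severity": "hard",
                       "message": f"ages outside the 5-9 y scope: {bad}"})
    bad_tags = set(recall["dairy_tag"].fillna("")) - set(DAIRY_TAGS) - {""}
    if bad_tags:
        issues.append({"severity": "hard",
                       "message": f"unknown dairy tags: {sorted(bad_tags)}"})
    return issues


def _table1(childday: pd.DataFrame, rule: ServingRule) -> pd.DataFrame:
    """Dairy-consumption analogue of a survey's descriptive dairy table."""
    n = len(childday)
    rows = []
    groups = [("total_dairy", childday["dairy_g"])]
    milk_all = childday[[f"g_{t}" for t in
                         ("milk_buffalo", "milk_cow", "milk_goat",
                          "milk_fortified", "tea_milk")]].sum(axis=1)
    groups.append(("all_milk", milk_all))
    for t in DAIRY_TAGS:
        groups.append((t, childday[f"g_{t}"]))
    for name, g in groups:
        consumers = g[g > 0]
        nc = len(consumers)
        rows.append({
            "item": name, "n_consumers": nc,
            "pct_consumers": round(100.0 * nc / n, 1) if n else np.nan,
            "mean_g": round(consumers.mean(), 1) if nc else 0.0,
            "sd_g": round(consumers.std(ddof=1), 1) if nc > 1 else 0.0,
            "max_g": round(g.max(), 1),
            "mean_servings": round(consumers.mean() / rule.grams_per_serving, 1)
            if nc else 0.0,
        })
    return pd.DataFrame(rows)


def _prevalence_fn(refs, req_dist):
    def fn(table: pd.DataFrame, nutrient: str) -> float:
        if nutrient == "iron_mg":
            rni = adequacy_stats.per_child_reference(table, nutrient, "rni", refs)
            return adequacy_stats.full_probability_prevalence(
                table[nutrient], rni, req_dist)
        ear = adequacy_stats.per_child_reference(table, nutrient, "ear", refs)
        return adequacy_stats.ear_cutpoint_prevalence(table[nutrient], ear)
    return fn


def _plot_prevalence(cmp_df: pd.DataFrame, title: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = cmp_df.dropna(subset=["baseline_pct"])
    x = np.arange(len(d))
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.bar(x - 0.2, d["baseline_pct"], width=0.4, label="baseline")
    ax.bar(x + 0.2, d["scenario_pct"], width=0.4, label="scenario")
    ax.set_xticks(x)
    ax.set_xticklabels(d.index, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("% inadequate")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole diet-modeling pipeline; returns the result bundle.

    Bundle keys: ``childday`` (post-exclusion), ``table1``, ``baseline``
    adequacy, per-scenario adequacy and reduction tables, ``sensitivity``
    and ``manifest``.  All tables are also written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = load_references(config.references_path)
    milks = load_milks(config.milks_path)
    rule = ServingRule()

    if config.recall_path:
        recall = pd.read_csv(config.recall_path,
                             dtype={"dairy_tag": str}, keep_default_na=False,
                             na_values=[])
        recall["grams"] = recall["grams"].astype(float)
        recall["age"] = recall["age"].astype(int)
        foods = pd.read_csv(config.foods_path)
        foods["dairy_tag"] = foods.get("dairy_tag", "").fillna("")
    else:
        recall, foods, truth = generate_survey(config.population,
                                               seed=config.seed)
        recall.to_csv(outdir / "recall.csv", index=False)
        foods.to_csv(outdir / "foods.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)

    issues = validate_inputs(recall, foods)
    hard = [i for i in issues if i["severity"] == "hard"]
    if hard:
        raise DietmodError(f"input validation failed: {hard}")

    childday = intake_engine.compute_intakes(recall, foods, serving_rule=rule)
    n0 = len(childday)
    childday, n_excluded = intake_engine.flag_energy_outliers(childday)
    childday = childday[~childday["energy_outlier"]].reset_index(drop=True)
    log.info("intakes: %d children, %d energy outliers excluded", n0, n_excluded)
    childday.to_csv(outdir / "childday.csv", index=False)

    table1 = _table1(childday, rule)
    table1.to_csv(outdir / "table1_dairy.csv", index=False)

    req_dist = adequacy_stats.RequirementDistribution()
    bundle: dict = {"childday": childday, "table1": table1}
    counts = {"n_children": n0, "n_energy_outliers": n_excluded,
              "n_analysis": len(childday)}

    scenario_tables: dict[str, pd.DataFrame] = {}
    for spec in config.scenarios:
        modified, mask = scenario_engine.apply_scenario(childday, spec, milks, rule)
        counts[f"n_eligible_{spec.name}"] = int(mask.sum())
        base_sub = adequacy_stats.summarize_adequacy(
            childday.loc[mask], refs, config.usual, req_dist,
            label=f"baseline_{spec.name}")
        after = adequacy_stats.summarize_adequacy(
            modified, refs, config.usual, req_dist, label=spec.name)
        amount_b = base_sub[base_sub["basis"] == "amount"]
        amount_a = after[after["basis"] == "amount"]
        cmp_df = adequacy_stats.compare_scenarios(amount_b, amount_a)
        scenario_tables[spec.name] = after
        bundle[f"adequacy_{spec.name}"] = after
        bundle[f"baseline_{spec.name}"] = base_sub
        bundle[f"reductions_{spec.name}"] = cmp_df
        base_sub.to_csv(outdir / f"adequacy_baseline_{spec.name}.csv", index=False)
        after.to_csv(outdir / f"adequacy_{spec.name}.csv", index=False)
        cmp_df.to_csv(outdir / f"reductions_{spec.name}.csv")
        if config.make_plots:
            _plot_prevalence(cmp_df, f"Inadequacy before/after {spec.name}",
                             outdir / f"fig_{spec.name}.png")

    baseline = adequacy_stats.summarize_adequacy(
        childday, refs, config.usual, req_dist, label="baseline")
    baseline.to_csv(outdir / "adequacy_baseline.csv", index=False)
    bundle["baseline"] = baseline

    if config.sweep_ratios:
        sweep = usual_intake.sensitivity_sweep(
            childday, config.sweep_nutrients, config.sweep_ratios,
            _prevalence_fn(refs, req_dist), config.usual)
        sweep.to_csv(outdir / "sensitivity.csv")
        bundle["sensitivity"] = sweep

    cfg_json = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
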