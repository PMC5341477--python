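"""End-to-end orchestration: generate (or load) recalls, build composites,
run substitution models, estimate intakes, score HEI-2010 and produce
publication-style comparison tables.

The result bundle contains:
  snack_shares    percent of solid-food snack calories by category and model
  means           observed/modeled population means with 95% CI (BRR SE),
                  percent change, significance stars and effect class,
                  overall and by age group
  hei             HEI-2010 total and component scores per dataset
  thresholds      percent of the population below/above intake thresholds
                  (sodium 2,300 mg/d; fiber 25 g/d) from the usual-intake
                  model
  replaced_by_age survey-weighted mean replaced snack energy by age group
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hei as hei_mod
from .composite import build_composite, load_nut_items
from .inference import (build_brr_weights, classify_effect, percent_change,
                        significance_stars, weighted_ttest)
from .recalls import NUTRIENT_COLS, daily_totals_table, write_recalls
from .substitution import model1, model2, run_models
from .synthetic import GeneratorConfig, generate_dataset
from .usual_intake import fit_amount_model, usual_distribution

logger = logging.getLogger(__name__)

#: outcome columns reported in the means tables (day-total scale)
DEFAULT_OUTCOMES = NUTRIENT_COLS + [
    "added_sugars_tsp", "solid_fats_g", "oils_g", "empty_calories_kcal",
]

DEFAULT_MODELS = (
    ("model1", "tree_nut"), ("model2", "tree_nut"),
    ("model1", "almond_only"), ("model2", "almond_only"),
)


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    models: tuple = DEFAULT_MODELS
    outcomes: list = field(default_factory=lambda: list(DEFAULT_OUTCOMES))
    sodium_threshold_mg: float = 2300.0
    fiber_threshold_g: float = 25.0
    by_age_group: bool = True
    usual_intake_nutrients: tuple = ("sodium_mg", "fiber_g")
    seed: int = 0
    rho: float = 0.7
    n_replicates: int = 32
    output_dir: str | Path | None = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("at least one substitution model is required")
        if self.sodium_threshold_mg <= 0 or self.fiber_threshold_g <= 0:
            raise ValueError("thresholds must be positive")


def _model_name(model: str, variant: str) -> str:
    return f"{model}_{variant}"


def _day_totals_with_empty_calories(foods: pd.DataFrame) -> pd.DataFrame:
    totals = daily_totals_table(foods)
    totals["empty_calories_kcal"] = (
        hei_mod.KCAL_PER_G_SOLID_FAT * totals["solid_fats_g"]
        + hei_mod.KCAL_PER_TSP_ADDED_SUGAR * totals["added_sugars_tsp"])
    return totals


def _person_means(totals: pd.DataFrame, persons: pd.DataFrame,
                  cols) -> pd.DataFrame:
    pm = totals.groupby("person_id")[list(cols)].mean()
    return pm.reindex(persons["person_id"]).fillna(0.0)


def snack_share_table(audits: dict[str, pd.DataFrame],
                      persons: pd.DataFrame) -> pd.DataFrame:
    """Percent of solid-food snack calories by category per model's
    eligible set (survey-weighted)."""
    w = persons.set_index("person_id")["survey_weight"]
    out = {}
    for name, audit in audits.items():
        elig = audit[audit["eligible"]].copy()
        elig["wkcal"] = elig["energy_kcal"] * elig["person_id"].map(w)
        shares = elig.groupby("category")["wkcal"].sum()
        out[name] = 100.0 * shares / shares.sum()
    return pd.DataFrame(out).fillna(0.0).sort_values(
        by=list(out), ascending=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the result bundle.

    Fully reproducible given config.seed (which also seeds the generator
    unless the generator carries its own seed).
    """
    gen = config.generator
    logger.info("pipeline: n=%d persons, models=%s, rho=%.2f, R=%d, "
                "thresholds sodium<%g mg/d fiber>%g g/d",
                gen.n_persons, list(config.models), config.rho,
                config.n_replicates, config.sodium_threshold_mg,
                config.fiber_threshold_g)
    persons, foods, days = generate_dataset(gen)
    scheme = build_brr_weights(persons, rho=config.rho,
                               n_replicates=config.n_replicates)
    items = load_nut_items()
    composites = {v: build_composite(items, v)
                  for v in {variant for _, variant in config.models}}
    models = {}
    for m, variant in config.models:
        comp = composites[variant]
        models[_model_name(m, variant)] = model1(comp) if m == "model1" \
            else model2(comp)

    results = run_models(foods, persons, models)
    datasets = {"observed": foods}
    datasets.update({name: res["foods"] for name, res in results.items()})

    totals = {name: _day_totals_with_empty_calories(f)
              for name, f in datasets.items()}
    pmeans = {name: _person_means(t, persons, config.outcomes)
              for name, t in totals.items()}
    age = persons.set_index("person_id")["age_group"]

    # --- means, CIs, percent change, effect classes ---------------------
    rows = []
    groups = [("all", None)]
    if config.by_age_group:
        groups += [(g, g) for g in persons["age_group"].unique()]
    full_w = scheme.full_weights
    for label, g in groups:
        sel = np.ones(len(persons), dtype=bool) if g is None \
            else (age.to_numpy() == g)
        for outcome in config.outcomes:
            obs_vals = pmeans["observed"][outcome].to_numpy()

            def est(wts, vals):
                return float(np.average(vals[sel], weights=wts[sel]))

            from .inference import brr_variance
            obs_mean, obs_se = brr_variance(lambda w: est(w, obs_vals), scheme)
            rows.append({"group": label, "outcome": outcome,
                         "dataset": "observed", "mean": obs_mean,
                         "se": obs_se,
                         "ci_lo": obs_mean - 1.96 * obs_se,
                         "ci_hi": obs_mean + 1.96 * obs_se,
                         "pct_change": 0.0, "p_value": np.nan,
                         "stars": "", "effect_class": ""})
            for name in results:
                vals = pmeans[name][outcome].to_numpy()
                mean, se = brr_variance(lambda w: est(w, vals), scheme)
                t, p = weighted_ttest(obs_mean, obs_se, mean, se)
                pct = percent_change(obs_mean, mean) if obs_mean != 0 else np.nan
                eff = classify_effect(pct, p) if np.isfinite(pct) else None
                rows.append({"group": label, "outcome": outcome,
                             "dataset": name, "mean": mean, "se": se,
                             "ci_lo": mean - 1.96 * se,
                             "ci_hi": mean + 1.96 * se,
                             "pct_change": pct, "p_value": p,
                             "stars": significance_stars(p),
                             "effect_class": eff.label if eff else ""})
    means = pd.DataFrame(rows)

    # --- HEI-2010 (population ratio, day 1) -----------------------------
    weights_map = persons.set_index("person_id")["survey_weight"]
    standards = hei_mod.load_standards()
    hei_rows = []
    hei_groups = [("all", None)]
    if config.by_age_group:
        hei_groups += [(g, g) for g in persons["age_group"].unique()]
    for name, f in datasets.items():
        for label, g in hei_groups:
            sub = f if g is None else f[
                f["person_id"].map(age).eq(g)]
            res = hei_mod.hei_score(sub, weights_map, standards)
            row = {"dataset": name, "group": label, "total": res.total}
            row.update(res.component_scores)
            hei_rows.append(row)
    hei_table = pd.DataFrame(hei_rows)

    # --- threshold attainment from the usual-intake model ----------------
    day_cov = days.set_index(["person_id", "recall_day"])
    thr_rows = []
    for name, t in totals.items():
        merged = t.set_index(["person_id", "recall_day"]).join(day_cov)
        merged["weight"] = merged.index.get_level_values(0).map(weights_map)
        for nutrient in config.usual_intake_nutrients:
            df = (merged.reset_index()[["person_id", nutrient, "weekend",
                                        "sequence", "weight"]]
                  .rename(columns={nutrient: "intake"}))
            model = fit_amount_model(df, nutrient=nutrient)
            below = (config.sodium_threshold_mg,) \
                if nutrient == "sodium_mg" else ()
            above = (config.fiber_threshold_g,) \
                if nutrient == "fiber_g" else ()
            dist = usual_distribution(model, seed=config.seed,
                                      thresholds_below=below,
                                      thresholds_above=above)
            row = {"dataset": name, "nutrient": nutrient,
                   "usual_mean": dist.mean, "lambda": model.lam}
            for c, v in dist.pct_below.items():
                row["pct_below"] = v
                row["threshold"] = c
            for c, v in dist.pct_above.items():
                row["pct_above"] = v
                row["threshold"] = c
            thr_rows.append(row)
    thresholds = pd.DataFrame(thr_rows)

    bundle = {
        "persons": persons, "foods": foods, "days": days,
        "snack_shares": snack_share_table(
            {n: r["audit"] for n, r in results.items()}, persons),
        "means": means,
        "hei": hei_table,
        "thresholds": thresholds,
        "replaced_by_age": pd.DataFrame(
            {n: r["replaced_by_age"] for n, r in results.items()}),
        "modified": {n: r["foods"] for n, r in results.items()},
    }

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_recalls(persons, foods, outdir / "foods.csv",
                      outdir / "persons.csv")
        for key in ("snack_shares", "means", "hei", "thresholds",
                    "replaced_by_age"):
            bundle[key].to_csv(outdir / f"{key}.csv")
        manifest = {
            "seed": config.seed, "n_persons": gen.n_persons,
            "models": [list(m) for m in config.models],
            "rho": config.rho, "n_replicates": config.n_replicates,
            "sodium_threshold_mg": config.sodium_threshold_mg,
            "fiber_threshold_g": config.fiber_threshold_g,
            "usual_intake_nutrients": list(config.usual_intake_nutrients),
            "composite_weights": {v: c.weights
                                  for v, c in composites.items()},
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)
    return bundle
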