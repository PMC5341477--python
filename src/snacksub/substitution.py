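"""Isocaloric replacement of between-meal solid snacks with a nut composite.

Two replacement rules are supported.  Model 1 replaces every solid food
eaten at a snack occasion; Model 2 additionally exempts snacks that are
already nutrient-dense: whole fruit, non-starchy vegetables, and grain
foods whose grain content is more than 50% whole grain (popcorn counts as
a whole grain).  Beverages and beverage additions (e.g. sugar stirred into
coffee) are never replaced, nor are tree-nut snacks themselves, and people
whose snacks are exclusively tree nuts keep their diets unchanged.
Replacement is calorie-for-calorie, so each person-day's total energy is
conserved exactly and only diet composition changes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composite import CompositeProfile, PROFILE_COLS
from .recalls import FOOD_COLS

MODEL2_EXEMPTIONS = frozenset(
    {"whole_fruit", "non_starchy_vegetables", "whole_grain_majority"})

#: categories treated as whole fruit for the Model 2 exemption
WHOLE_FRUIT_CATEGORIES = frozenset({"apples", "bananas", "other_fruits"})

#: non-starchy vegetable categories; the snack vocabulary has no dedicated
#: vegetable category, so this is configurable for user-supplied data
NON_STARCHY_VEG_CATEGORIES: frozenset = frozenset()


@dataclass(frozen=True)
class SubstitutionModel:
    name: str
    composite: CompositeProfile
    exemptions: frozenset = frozenset()
    whole_fruit_categories: frozenset = WHOLE_FRUIT_CATEGORIES
    non_starchy_veg_categories: frozenset = NON_STARCHY_VEG_CATEGORIES

    def __post_init__(self):
        if self.name == "model1" and self.exemptions:
            raise ValueError("model1 has no exemptions")
        if self.name == "model2" and self.exemptions != MODEL2_EXEMPTIONS:
            raise ValueError(f"model2 exemptions must be {set(MODEL2_EXEMPTIONS)}")
        if self.name not in ("model1", "model2"):
            raise ValueError("model name must be model1 or model2")


def model1(composite: CompositeProfile) -> SubstitutionModel:
    return SubstitutionModel("model1", composite)


def model2(composite: CompositeProfile, **kwargs) -> SubstitutionModel:
    return SubstitutionModel("model2", composite, MODEL2_EXEMPTIONS, **kwargs)


@dataclass(frozen=True)
class SubstitutionResult:
    person_id: str
    recall_day: int
    replaced_energy_kcal: float
    records: pd.DataFrame
    audit: list = field(default_factory=list)


def eligibility_mask(foods: pd.DataFrame, model: SubstitutionModel):
    """Vectorized eligibility: (boolean mask, reason string per row).

    A record is eligible iff it is a solid food at a snack occasion, is not
    itself a tree nut, and (for model 2) is not an exempt whole-fruit /
    non-starchy-vegetable / majority-whole-grain snack.
    """
    reason = pd.Series("eligible", index=foods.index)
    reason[foods["occasion"].eq("meal")] = "meal"
    reason[foods["occasion"].eq("beverage_addition")] = "beverage_addition"
    snack = foods["occasion"].eq("snack")
    reason[snack & foods["is_beverage"]] = "beverage"
    reason[snack & ~foods["is_beverage"] & foods["is_tree_nut"]] = "tree_nut"
    if model.name == "model2":
        open_ = reason.eq("eligible")
        wf = foods["category"].isin(model.whole_fruit_categories)
        veg = foods["category"].isin(model.non_starchy_veg_categories)
        wg = foods["whole_grain_fraction"] > 0.5
        reason[open_ & wf] = "whole_fruit"
        reason[open_ & ~wf & veg] = "non_starchy_vegetables"
        reason[open_ & ~wf & ~veg & wg] = "whole_grain_majority"
    return reason.eq("eligible"), reason


def is_eligible(record, model: SubstitutionModel):
    """Eligibility of a single record (FoodRecord, Series or dict)."""
    if hasattr(record, "as_row"):
        record = record.as_row()
    df = pd.DataFrame([dict(record)])
    mask, reason = eligibility_mask(df, model)
    return bool(mask.iloc[0]), str(reason.iloc[0])


def exclusive_nut_snacker(records: pd.DataFrame) -> bool:
    """True iff every solid snack the person reported is a tree nut.

    Beverages at snack occasions are disregarded; a person with no solid
    snack at all is not flagged (there is nothing to replace either way).
    Evaluated across all of the person's recall days.
    """
    solid_snacks = records[records["occasion"].eq("snack")
                           & ~records["is_beverage"]]
    return len(solid_snacks) > 0 and bool(solid_snacks["is_tree_nut"].all())


def exclusive_nut_snacker_flags(foods: pd.DataFrame) -> pd.Series:
    """Person-level exclusive-nut-snacker flags, indexed by person_id."""
    solid = foods["occasion"].eq("snack") & ~foods["is_beverage"]
    g = foods.loc[solid].groupby("person_id")["is_tree_nut"]
    flags = g.all() & (g.count() > 0)
    out = pd.Series(False, index=pd.Index(foods["person_id"].unique(),
                                          name="person_id"))
    out[flags.index] = flags
    return out


def _composite_row(person_id, day, energy, model: SubstitutionModel) -> dict:
    scale = energy / 100.0
    row = {"person_id": person_id, "recall_day": day, "occasion": "snack",
           "is_beverage": False, "category": "other", "is_tree_nut": True,
           "whole_grain_fraction": 0.0, "energy_kcal": energy}
    for c in PROFILE_COLS:
        row[c] = model.composite.per_100kcal.get(c, 0.0) * scale
    return row


def substitute_day(records: pd.DataFrame, model: SubstitutionModel,
                   exempt: bool = False) -> SubstitutionResult:
    """Replace one person-day's eligible snack energy with the composite.

    The eligible records are removed and one composite record of equal
    total energy is added (nutrients and components scaled linearly from
    the per-100-kcal profile), so day energy is conserved exactly.  If the
    person is an exclusive nut snacker (``exempt``), or no energy is
    eligible, the day passes through unchanged.
    """
    pid = records["person_id"].iloc[0] if len(records) else ""
    day = int(records["recall_day"].iloc[0]) if len(records) else 0
    if records["person_id"].nunique() > 1 or records["recall_day"].nunique() > 1:
        raise ValueError("substitute_day expects a single person-day")
    mask, reason = eligibility_mask(records, model)
    if exempt:
        mask = pd.Series(False, index=records.index)
        reason = pd.Series("exclusive_nut_snacker", index=records.index)
    audit = list(zip(records.index, mask, reason))
    replaced = float(records.loc[mask, "energy_kcal"].sum())
    if replaced <= 0:
        return SubstitutionResult(pid, day, 0.0, records.copy(), audit)
    kept = records.loc[~mask]
    comp = pd.DataFrame([_composite_row(pid, day, replaced, model)],
                        columns=FOOD_COLS)
    out = pd.concat([kept, comp], ignore_index=True)
    return SubstitutionResult(pid, day, replaced, out, audit)


def substitute_dataset(foods: pd.DataFrame, model: SubstitutionModel):
    """Apply a substitution model to a whole foods table (vectorized).

    Returns (modified foods table, audit table).  The audit table carries
    one row per input record with its eligibility decision and reason;
    exclusive nut snackers are exempted person-wide.
    """
    flags = exclusive_nut_snacker_flags(foods)
    exempt = foods["person_id"].map(flags).fillna(False).astype(bool)
    mask, reason = eligibility_mask(foods, model)
    reason = reason.where(~exempt, "exclusive_nut_snacker")
    mask = mask & ~exempt
    audit = pd.DataFrame({
        "person_id": foods["person_id"], "recall_day": foods["recall_day"],
        "category": foods["category"], "energy_kcal": foods["energy_kcal"],
        "eligible": mask, "reason": reason})

    replaced = (foods.loc[mask]
                .groupby(["person_id", "recall_day"], sort=False)["energy_kcal"]
                .sum().reset_index())
    replaced = replaced[replaced["energy_kcal"] > 0]
    comp = pd.DataFrame({
        "person_id": replaced["person_id"],
        "recall_day": replaced["recall_day"],
        "occasion": "snack", "is_beverage": False, "category": "other",
        "is_tree_nut": True, "whole_grain_fraction": 0.0,
        "energy_kcal": replaced["energy_kcal"]})
    scale = replaced["energy_kcal"].to_numpy() / 100.0
    for c in PROFILE_COLS:
        comp[c] = model.composite.per_100kcal.get(c, 0.0) * scale
    out = pd.concat([foods.loc[~mask], comp[FOOD_COLS]], ignore_index=True)
    return out, audit


def run_models(foods: pd.DataFrame, persons: pd.DataFrame,
               models: dict[str, SubstitutionModel]):
    """Run several substitution models over one dataset.

    Returns a dict name -> {"foods": modified table, "audit": audit table,
    "replaced_by_age": survey-weighted mean replaced energy per day by age
    group}.
    """
    results = {}
    meta = persons.set_index("person_id")
    for name, model in models.items():
        modified, audit = substitute_dataset(foods, model)
        rep = (audit[audit["eligible"]]
               .groupby(["person_id", "recall_day"])["energy_kcal"].sum())
        per_person = rep.groupby("person_id").mean()
        per_person = per_person.reindex(meta.index, fill_value=0.0)
        w = meta["survey_weight"]
        df = pd.DataFrame({"age_group": meta["age_group"],
                           "replaced": per_person, "w": w})
        by_age = (df.groupby("age_group", sort=False)
                  .apply(lambda d: np.average(d["replaced"], weights=d["w"]),
                         include_groups=False)
                  .rename("mean_replaced_kcal"))
        results[name] = {"foods": modified, "audit": audit,
                         "replaced_by_age": by_age}
    return results
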