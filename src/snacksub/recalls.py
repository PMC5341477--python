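"""Domain types and delimited-text I/O for 24-h recall data.

The canonical in-memory containers are pandas DataFrames with fixed column
schemas (one food per row in the foods table, one person per row in the
persons table); small frozen dataclasses are provided for row-level
construction and validation.  All downstream stages (substitution,
usual-intake estimation, HEI scoring, survey inference) consume these
tables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: nutrient columns, units fixed as reported: grams except ALA (mg),
#: sodium/potassium/magnesium (mg)
NUTRIENT_COLS = [
    "total_fat_g", "sfa_g", "mufa_g", "pufa_g", "ala_mg",
    "protein_g", "carbohydrate_g", "fiber_g",
    "sodium_mg", "potassium_mg", "magnesium_mg",
]

#: food-pattern component columns (FPED-style equivalents)
COMPONENT_COLS = [
    "added_sugars_tsp", "solid_fats_g", "oils_g",
    "whole_grain_oz", "refined_grain_oz",
    "total_fruit_cup", "whole_fruit_cup",
    "total_veg_cup", "greens_beans_cup",
    "dairy_cup", "protein_foods_oz", "seafood_plant_protein_oz",
]

FOOD_META_COLS = [
    "person_id", "recall_day", "occasion", "is_beverage", "category",
    "is_tree_nut", "whole_grain_fraction", "energy_kcal",
]
FOOD_COLS = FOOD_META_COLS + NUTRIENT_COLS + COMPONENT_COLS

PERSON_COLS = [
    "person_id", "age_years", "age_group", "survey_weight",
    "stratum_id", "psu_id", "n_recalls",
]

OCCASIONS = ("meal", "snack", "beverage_addition")

#: age bands used throughout the reporting, (label, low, high) in years
AGE_GROUPS = [
    ("1-3", 1, 3), ("4-8", 4, 8), ("9-13", 9, 13), ("14-19", 14, 19),
    ("20-30", 20, 30), ("31-50", 31, 50), ("51-70", 51, 70),
    ("71+", 71, 200),
]
AGE_GROUP_LABELS = [g[0] for g in AGE_GROUPS]

#: snack food-category vocabulary (What-We-Eat-in-America style groups)
CATEGORIES = [
    "cookies_brownies", "ice_cream_frozen_dairy", "cakes_pies",
    "candy_chocolate", "tortilla_corn_chips", "candy_not_chocolate",
    "crackers", "potato_chips", "doughnuts_pastries", "popcorn",
    "cheese", "yeast_breads", "apples", "pretzels_snack_mix", "bananas",
    "pizza", "rte_cereal_higher_sugar", "cereal_bars", "yogurt_lowfat",
    "biscuits_muffins", "cold_cuts", "other_fruits", "burritos_tacos",
    "other",
]

# fat-subclass closure tolerance: SFA+MUFA+PUFA may exceed total fat only
# by rounding slack
FAT_CLOSURE_TOL = 0.05


def age_group_for(age_years: float) -> str:
    """Map an age in years to its reporting band."""
    for label, lo, hi in AGE_GROUPS:
        if lo <= age_years <= hi:
            return label
    raise ValueError(f"age {age_years} outside supported range (>=1 y)")


@dataclass(frozen=True)
class NutrientVector:
    total_fat_g: float = 0.0
    sfa_g: float = 0.0
    mufa_g: float = 0.0
    pufa_g: float = 0.0
    ala_mg: float = 0.0
    protein_g: float = 0.0
    carbohydrate_g: float = 0.0
    fiber_g: float = 0.0
    sodium_mg: float = 0.0
    potassium_mg: float = 0.0
    magnesium_mg: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"nutrient {f.name} negative: {v}")
        closure = self.sfa_g + self.mufa_g + self.pufa_g
        if closure > self.total_fat_g * (1 + FAT_CLOSURE_TOL) + 1e-9:
            raise ValueError(
                f"fat subclasses ({closure:.3f} g) exceed total fat "
                f"({self.total_fat_g:.3f} g) beyond tolerance")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in NUTRIENT_COLS])


@dataclass(frozen=True)
class ComponentVector:
    added_sugars_tsp: float = 0.0
    solid_fats_g: float = 0.0
    oils_g: float = 0.0
    whole_grain_oz: float = 0.0
    refined_grain_oz: float = 0.0
    total_fruit_cup: float = 0.0
    whole_fruit_cup: float = 0.0
    total_veg_cup: float = 0.0
    greens_beans_cup: float = 0.0
    dairy_cup: float = 0.0
    protein_foods_oz: float = 0.0
    seafood_plant_protein_oz: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"component {f.name} negative")
        if self.whole_fruit_cup > self.total_fruit_cup + 1e-9:
            raise ValueError("whole_fruit_cup exceeds total_fruit_cup")
        if self.greens_beans_cup > self.total_veg_cup + 1e-9:
            raise ValueError("greens_beans_cup exceeds total_veg_cup")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COMPONENT_COLS])


@dataclass(frozen=True)
class Person:
    person_id: str
    age_years: float
    survey_weight: float
    stratum_id: str
    psu_id: str
    n_recalls: int
    age_group: str = ""

    def __post_init__(self):
        if self.age_years < 1:
            raise ValueError("age_years must be >= 1")
        if self.survey_weight <= 0:
            raise ValueError("survey_weight must be positive")
        if self.n_recalls not in (1, 2):
            raise ValueError("n_recalls must be 1 or 2")
        expected = age_group_for(self.age_years)
        if self.age_group == "":
            object.__setattr__(self, "age_group", expected)
        elif self.age_group != expected:
            raise ValueError(
                f"age_group {self.age_group!r} inconsistent with "
                f"age {self.age_years} (expected {expected!r})")


@dataclass(frozen=True)
class FoodRecord:
    person_id: str
    recall_day: int
    occasion: str
    is_beverage: bool
    category: str
    energy_kcal: float
    is_tree_nut: bool = False
    whole_grain_fraction: float = 0.0
    nutrients: NutrientVector = field(default_factory=NutrientVector)
    components: ComponentVector = field(default_factory=ComponentVector)

    def __post_init__(self):
        if self.recall_day not in (1, 2):
            raise ValueError("recall_day must be 1 or 2")
        if self.occasion not in OCCASIONS:
            raise ValueError(f"occasion must be one of {OCCASIONS}")
        if self.energy_kcal < 0:
            raise ValueError("energy_kcal must be nonnegative")
        if not 0 <= self.whole_grain_fraction <= 1:
            raise ValueError("whole_grain_fraction must be in [0, 1]")
        if self.category not in CATEGORIES:
            logger.warning("unknown category %r mapped to 'other'",
                           self.category)
            object.__setattr__(self, "category", "other")

    def as_row(self) -> dict:
        row = {c: getattr(self, c) for c in FOOD_META_COLS}
        row.update({c: getattr(self.nutrients, c) for c in NUTRIENT_COLS})
        row.update({c: getattr(self.components, c) for c in COMPONENT_COLS})
        return row


@dataclass(frozen=True)
class DailyIntake:
    person_id: str
    recall_day: int
    energy_kcal: float
    nutrients: NutrientVector
    components: ComponentVector
    snack_energy_kcal: float
    eligible_snack_energy_kcal: float = float("nan")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """One or more rows violate a domain invariant."""


def foods_frame(records: Iterable[FoodRecord]) -> pd.DataFrame:
    """Assemble FoodRecord objects into the canonical foods table."""
    rows = [r.as_row() for r in records]
    if not rows:
        return pd.DataFrame(columns=FOOD_COLS)
    return pd.DataFrame(rows, columns=FOOD_COLS)


def validate_foods(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a foods table; returns the table with canonical dtypes.

    Raises SchemaError for missing columns and ValidationError naming the
    offending rows for invariant violations.  Unknown categories are mapped
    to "other" with a logged warning rather than rejected.
    """
    missing = [c for c in FOOD_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"foods table missing columns: {missing}")
    df = df.copy()
    df["recall_day"] = df["recall_day"].astype(int)
    df["is_beverage"] = df["is_beverage"].astype(bool)
    df["is_tree_nut"] = df["is_tree_nut"].astype(bool)
    for c in ["whole_grain_fraction", "energy_kcal"] + NUTRIENT_COLS + COMPONENT_COLS:
        df[c] = df[c].astype(float)

    problems = []

    def check(mask: pd.Series, msg: str):
        if mask.any():
            rows = list(df.index[mask][:5])
            problems.append(f"{msg} (rows {rows}{'...' if mask.sum() > 5 else ''})")

    check(~df["recall_day"].isin([1, 2]), "recall_day not in {1,2}")
    check(~df["occasion"].isin(OCCASIONS), f"occasion not in {OCCASIONS}")
    check(df["energy_kcal"] < 0, "negative energy_kcal")
    check((df["whole_grain_fraction"] < 0) | (df["whole_grain_fraction"] > 1),
          "whole_grain_fraction outside [0,1]")
    for c in NUTRIENT_COLS + COMPONENT_COLS:
        check(df[c] < 0, f"negative {c}")
    closure = df["sfa_g"] + df["mufa_g"] + df["pufa_g"]
    check(closure > df["total_fat_g"] * (1 + FAT_CLOSURE_TOL) + 1e-9,
          "fat subclasses exceed total fat beyond tolerance")
    check(df["whole_fruit_cup"] > df["total_fruit_cup"] + 1e-9,
          "whole_fruit_cup exceeds total_fruit_cup")
    check(df["greens_beans_cup"] > df["total_veg_cup"] + 1e-9,
          "greens_beans_cup exceeds total_veg_cup")
    if problems:
        raise ValidationError("; ".join(problems))

    unknown = ~df["category"].isin(CATEGORIES)
    if unknown.any():
        logger.warning("%d rows with unknown category mapped to 'other'",
                       int(unknown.sum()))
        df.loc[unknown, "category"] = "other"
    return df[FOOD_COLS]


def validate_persons(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PERSON_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"persons table missing columns: {missing}")
    df = df.copy()
    df["age_years"] = df["age_years"].astype(float)
    df["survey_weight"] = df["survey_weight"].astype(float)
    df["n_recalls"] = df["n_recalls"].astype(int)
    problems = []
    if (df["age_years"] < 1).any():
        problems.append("age_years < 1")
    if (df["survey_weight"] <= 0).any():
        problems.append("nonpositive survey_weight")
    if (~df["n_recalls"].isin([1, 2])).any():
        problems.append("n_recalls not in {1,2}")
    expected = df["age_years"].map(age_group_for)
    bad = df["age_group"].astype(str) != expected
    if bad.any():
        problems.append(
            f"age_group inconsistent with age_years (rows {list(df.index[bad][:5])})")
    if df["person_id"].duplicated().any():
        problems.append("duplicate person_id")
    if problems:
        raise ValidationError("; ".join(problems))
    extra = [c for c in df.columns if c not in PERSON_COLS]
    return df[PERSON_COLS + extra]


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | str | Path | None) -> pd.DataFrame:
    """Rename user columns to canonical names via a mapping or a YAML file."""
    if schema is None:
        return df
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    return df.rename(columns={v: k for k, v in schema.items()})


def read_recalls(foods_path, persons_path, schema=None, persons_schema=None):
    """Read foods and persons CSV files into validated canonical tables.

    Parameters
    ----------
    foods_path, persons_path
        UTF-8 comma-delimited files, one food (resp. person) per row.
    schema, persons_schema
        Optional column maps (canonical name -> user column), given as a
        dict or a path to a YAML file.

    Returns
    -------
    (persons, foods) : tuple of DataFrame
    """
    foods = _apply_schema(
        pd.read_csv(foods_path, float_precision="round_trip"), schema)
    persons = _apply_schema(
        pd.read_csv(persons_path, float_precision="round_trip"), persons_schema)
    return validate_persons(persons), validate_foods(foods)


def write_recalls(persons: pd.DataFrame, foods: pd.DataFrame,
                  foods_path, persons_path) -> None:
    """Write canonical tables as UTF-8 CSV (full float precision)."""
    validate_persons(persons).to_csv(persons_path, index=False,
                                     float_format="%.17g")
    validate_foods(foods).to_csv(foods_path, index=False,
                                 float_format="%.17g")


def daily_totals(records: pd.DataFrame) -> DailyIntake:
    """Sum one person-day's food records into a DailyIntake.

    All records must share person_id and recall_day; an empty table is not
    attributable to a person-day and must be summed via daily_totals_table
    or constructed directly.
    """
    if len(records) == 0:
        return DailyIntake("", 0, 0.0, NutrientVector(), ComponentVector(), 0.0)
    pid = records["person_id"].unique()
    day = records["recall_day"].unique()
    if len(pid) > 1 or len(day) > 1:
        raise ValueError(
            f"records span multiple person-days: persons {list(pid)}, days {list(day)}")
    snack = records["occasion"].eq("snack")
    return DailyIntake(
        person_id=pid[0],
        recall_day=int(day[0]),
        energy_kcal=float(records["energy_kcal"].sum()),
        nutrients=NutrientVector(**{c: float(records[c].sum()) for c in NUTRIENT_COLS}),
        components=ComponentVector(**{c: float(records[c].sum()) for c in COMPONENT_COLS}),
        snack_energy_kcal=float(records.loc[snack, "energy_kcal"].sum()),
    )


def daily_totals_table(foods: pd.DataFrame) -> pd.DataFrame:
    """Vectorized person-day totals for a whole foods table.

    Returns one row per (person_id, recall_day) with summed energy,
    nutrients, components and snack energy.
    """
    value_cols = ["energy_kcal"] + NUTRIENT_COLS + COMPONENT_COLS
    g = foods.groupby(["person_id", "recall_day"], sort=False)
    out = g[value_cols].sum()
    snack_e = (foods["energy_kcal"].where(foods["occasion"].eq("snack"), 0.0)
               .groupby([foods["person_id"], foods["recall_day"]], sort=False).sum())
    out["snack_energy_kcal"] = snack_e
    return out.reset_index()
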