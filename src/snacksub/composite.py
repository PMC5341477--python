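"""Frequency-weighted nut composite construction.

The replacement food for the substitution models is a composite nut: each
nut item consumed in the population contributes in proportion to its
(survey-weighted) frequency of consumption, and the composite's nutrient /
food-pattern profile per 100 kcal is the weight-average of the item
profiles.  An almond-only variant restricts to almond items and
renormalizes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recalls import COMPONENT_COLS, NUTRIENT_COLS

PROFILE_COLS = NUTRIENT_COLS + COMPONENT_COLS

VARIANTS = ("tree_nut", "almond_only")


@dataclass(frozen=True)
class NutItem:
    """One nut food item with its consumption frequency and profile.

    per_100kcal maps nutrient/component column names to amounts per exactly
    100 kcal of the item; energy_density_kcal_per_g converts energy to mass.
    """
    item_id: str
    label: str
    is_almond: bool
    weighted_frequency: float
    energy_density_kcal_per_g: float
    per_100kcal: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.weighted_frequency < 0:
            raise ValueError("weighted_frequency must be nonnegative")
        if self.energy_density_kcal_per_g <= 0:
            raise ValueError("energy density must be positive")
        for k, v in self.per_100kcal.items():
            if v < 0:
                raise ValueError(f"per-100kcal entry {k} negative")


@dataclass(frozen=True)
class CompositeProfile:
    """Normalized item weights plus the blended per-100-kcal profile."""
    variant: str
    weights: dict[str, float]
    per_100kcal: dict[str, float]
    energy_density_kcal_per_g: float

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {total}, expected 1")

    def profile_array(self) -> np.ndarray:
        return np.array([self.per_100kcal.get(c, 0.0) for c in PROFILE_COLS])


def load_nut_items(path: str | Path | None = None) -> list[NutItem]:
    """Load nut items from a CSV (the packaged table if path is None)."""
    if path is None:
        path = resources.files("snacksub") / "data" / "nut_items.csv"
    df = pd.read_csv(path, comment="#")
    items = []
    for _, row in df.iterrows():
        items.append(NutItem(
            item_id=row["item_id"],
            label=row["label"],
            is_almond=bool(row["is_almond"]),
            weighted_frequency=float(row["weighted_frequency"]),
            energy_density_kcal_per_g=float(row["energy_density_kcal_per_g"]),
            per_100kcal={c: float(row[c]) for c in PROFILE_COLS},
        ))
    return items


def build_composite(items: list[NutItem], variant: str = "tree_nut") -> CompositeProfile:
    """Blend nut items into a composite by normalized consumption frequency.

    weight(item) = weighted_frequency / sum of weighted_frequency over the
    included items; almond_only restricts to is_almond items first.  The
    composite profile is the weighted average of the item per-100-kcal
    profiles; its energy density is the harmonic (mass-correct) mean.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "almond_only":
        items = [it for it in items if it.is_almond]
        if not items:
            raise ValueError("almond_only variant requires >=1 almond item")
    total = sum(it.weighted_frequency for it in items)
    if total <= 0:
        raise ValueError("all item frequencies are zero")
    weights = {it.item_id: it.weighted_frequency / total for it in items}
    profile = {c: sum(weights[it.item_id] * it.per_100kcal.get(c, 0.0)
                      for it in items)
               for c in PROFILE_COLS}
    # grams per 100 kcal of the blend = sum of weight * 100/density
    grams = sum(weights[it.item_id] * 100.0 / it.energy_density_kcal_per_g
                for it in items)
    return CompositeProfile(variant=variant, weights=weights,
                            per_100kcal=profile,
                            energy_density_kcal_per_g=100.0 / grams)


def composite_mass_for_energy(profile_or_density, energy_kcal: float) -> float:
    """Grams of nut supplying a given energy.

    Accepts a CompositeProfile or an energy density in kcal/g.  E.g. at an
    almond density of ~5.75 kcal/g, 293 kcal corresponds to ~51 g.
    """
    if isinstance(profile_or_density, CompositeProfile):
        density = profile_or_density.energy_density_kcal_per_g
    else:
        density = float(profile_or_density)
    if density <= 0:
        raise ValueError("energy density must be positive")
    if energy_kcal < 0:
        raise ValueError("energy must be nonnegative")
    return energy_kcal / density


def write_composite(profile: CompositeProfile, weights_path, profile_path) -> None:
    """Persist a composite as YAML weights plus a delimited profile table."""
    with open(weights_path, "w") as fh:
        yaml.safe_dump({"variant": profile.variant,
                        "energy_density_kcal_per_g": profile.energy_density_kcal_per_g,
                        "weights": profile.weights}, fh)
    pd.DataFrame([profile.per_100kcal]).to_csv(profile_path, index=False)
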