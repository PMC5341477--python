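"""HEI-2010 diet-quality scoring via the population ratio method.

The Healthy Eating Index-2010 scores a diet on 12 energy-adjusted
components (9 adequacy, 3 moderation) summing to 100 points.  Population
means are computed with the population ratio method: each component's
density is the ratio of the survey-weighted population total of the
component amount to the weighted population total of energy (first recall
day only), scaled to the component's basis — per 1,000 kcal, a fatty-acid
ratio, or percent of energy for empty calories (solid fats at 9 kcal/g
plus added sugars at 16 kcal/tsp).  Densities are then scored piecewise
linearly against fixed standards.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

KCAL_PER_G_SOLID_FAT = 9.0
KCAL_PER_TSP_ADDED_SUGAR = 16.0


@dataclass(frozen=True)
class ComponentStandard:
    name: str
    max_points: float
    direction: str        # "adequacy" | "moderation"
    basis: str            # per_1000_kcal | per_1000_kcal_g | ratio | pct_energy
    standard_for_max: float
    standard_for_min: float | None = None  # lower anchor; 0 for plain adequacy
    amount: str | None = None              # component column, None for derived

    def __post_init__(self):
        if self.direction not in ("adequacy", "moderation"):
            raise ValueError("direction must be adequacy or moderation")
        if self.direction == "moderation":
            if self.standard_for_min is None or \
                    self.standard_for_min <= self.standard_for_max:
                raise ValueError(
                    f"{self.name}: moderation needs standard_for_min > "
                    "standard_for_max")


@dataclass(frozen=True)
class HEIStandards:
    components: tuple[ComponentStandard, ...]

    def __post_init__(self):
        if len(self.components) != 12:
            raise ValueError("HEI-2010 has exactly 12 components")
        total = sum(c.max_points for c in self.components)
        if abs(total - 100) > 1e-9:
            raise ValueError(f"max points sum to {total}, expected 100")

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, name: str) -> ComponentStandard:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class HEIResult:
    total: float
    component_scores: dict[str, float]
    densities: dict[str, float]

    def __post_init__(self):
        if abs(self.total - sum(self.component_scores.values())) > 1e-9:
            raise ValueError("total must equal the sum of component scores")


def load_standards(path: str | Path | None = None) -> HEIStandards:
    """Load scoring standards from YAML (packaged defaults if path=None)."""
    if path is None:
        path = resources.files("snacksub") / "data" / "hei2010_standards.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    comps = []
    for name, c in raw["components"].items():
        comps.append(ComponentStandard(
            name=name, max_points=float(c["max_points"]),
            direction=c["direction"], basis=c["basis"],
            standard_for_max=float(c["standard_for_max"]),
            standard_for_min=(float(c["standard_for_min"])
                              if "standard_for_min" in c else None),
            amount=c.get("amount")))
    return HEIStandards(components=tuple(comps))


def _day1_nonzero(records: pd.DataFrame):
    """Restrict to first-recall records of persons with positive energy."""
    day1 = records[records["recall_day"] == 1]
    energy = day1.groupby("person_id")["energy_kcal"].sum()
    zero = energy[energy <= 0].index
    if len(zero):
        logger.info("HEI: excluding %d zero-energy persons", len(zero))
        day1 = day1[~day1["person_id"].isin(zero)]
    return day1


def population_ratio_density(records: pd.DataFrame, weights: pd.Series,
                             component: ComponentStandard) -> float:
    """Population-ratio density of one component from day-1 records.

    ``weights`` maps person_id to survey weight.  density =
    (sum_i w_i amount_i) / (sum_i w_i energy_i), scaled to the component's
    basis.
    """
    day1 = _day1_nonzero(records)
    w = day1["person_id"].map(weights).to_numpy(dtype=float)
    total_energy = float(np.sum(w * day1["energy_kcal"].to_numpy()))
    if total_energy <= 0:
        raise ValueError("zero total weighted energy")

    def wtot(col: str) -> float:
        return float(np.sum(w * day1[col].to_numpy(dtype=float)))

    if component.basis == "ratio":
        sfa = wtot("sfa_g")
        unsat = wtot("mufa_g") + wtot("pufa_g")
        if sfa <= 0:
            return np.inf if unsat > 0 else 0.0
        return unsat / sfa
    if component.basis == "pct_energy":
        sofas = (KCAL_PER_G_SOLID_FAT * wtot("solid_fats_g")
                 + KCAL_PER_TSP_ADDED_SUGAR * wtot("added_sugars_tsp"))
        return 100.0 * sofas / total_energy
    amount = wtot(component.amount)
    density = 1000.0 * amount / total_energy
    if component.basis == "per_1000_kcal_g":
        density /= 1000.0  # mg -> g per 1,000 kcal
    return density


def score_component(density: float, std: ComponentStandard) -> float:
    """Piecewise-linear HEI component score, clamped to [0, max_points].

    Adequacy: max points at density >= standard_for_max, prorated linearly
    down to the lower anchor (0 unless the component defines one, as the
    fatty-acid ratio does).  Moderation: max points at density <=
    standard_for_max, zero at density >= standard_for_min, linear between.
    """
    if density < 0:
        raise ValueError("negative density")
    lo = std.standard_for_min or 0.0
    if std.direction == "adequacy":
        if np.isinf(density):
            return std.max_points
        frac = (density - lo) / (std.standard_for_max - lo)
    else:
        frac = (std.standard_for_min - density) / \
            (std.standard_for_min - std.standard_for_max)
    return float(std.max_points * min(1.0, max(0.0, frac)))


def hei_score(records: pd.DataFrame, weights: pd.Series,
              standards: HEIStandards | None = None) -> HEIResult:
    """HEI-2010 total and component scores for a weighted population.

    Uses first-recall records only (single-recall population ratio
    method).  ``weights`` maps person_id to survey weight.
    """
    if standards is None:
        standards = load_standards()
    densities = {c.name: population_ratio_density(records, weights, c)
                 for c in standards}
    scores = {name: score_component(d, standards[name])
              for name, d in densities.items()}
    return HEIResult(total=float(sum(scores.values())),
                     component_scores=scores, densities=densities)
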