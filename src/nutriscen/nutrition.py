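"""Population-level nutrient supply and adequacy classification.

The food column of a balance sheet is converted to nutrients as eaten:
each commodity is disaggregated into food items with consumption
weights, adjusted for the inedible fraction and household waste, and
matched to food-composition densities per 100 g edible portion.  Total
supply is divided by the population and 365 days to give per-capita
daily supply.

Adequacy is judged against three ascending population-weighted
thresholds per nutrient:

* micronutrients and protein — Lower Reference Nutrient Intake (LRNI),
  Estimated Average Requirement (EAR) and Reference Nutrient Intake
  (RNI, the principal target);
* fat — minimum, min–max midpoint and maximum recommended intakes;
* energy — minimum, average and maximum dietary energy requirements,
  with supply at or above the maximum flagged as oversupply.

Band boundaries are lower-closed: supply exactly at a threshold falls
in the higher band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, DataError, ValidationError

#: Tracked nutrients and their per-100 g (densities) / per-day (requirements) units.
NUTRIENT_UNITS = {
    "energy": "kcal",
    "protein": "g",
    "fat": "g",
    "carbohydrate": "g",
    "saturated_fat": "g",
    "fibre": "g",
    "calcium": "mg",
    "zinc": "mg",
    "iron": "mg",
    "vitamin_c": "mg",
    "thiamin": "mg",
    "riboflavin": "mg",
    "niacin": "mg",
    "folate": "ug",
    "vitamin_b6": "mg",
    "vitamin_a": "ug_rae",  # optional, in retinol activity equivalents
}
NUTRIENTS = tuple(n for n in NUTRIENT_UNITS if n != "vitamin_a")

#: Nutrients carrying an LRNI/EAR/RNI band ("band1"); fat and energy
#: have their own three-threshold conventions.  Saturated fat is
#: tracked in supply but has no adequacy band.
BAND1_NUTRIENTS = tuple(
    n for n in NUTRIENT_UNITS if n not in ("energy", "fat", "saturated_fat")
)
REQUIRED_NUTRIENTS = tuple(n for n in NUTRIENT_UNITS if n != "saturated_fat")

BANDS = ("inadequate", "marginal_low", "marginal_high", "adequate", "oversupply")


@dataclass
class RequirementSet:
    """Population-weighted requirement thresholds per nutrient.

    ``thresholds`` is indexed by nutrient with ascending columns
    (low, mid, high) and a ``kind`` column in {band1, fat, energy}.
    The principal target is ``high`` (RNI) for band1 nutrients and
    ``mid`` (midpoint / average requirement) for fat and energy.
    """

    thresholds: pd.DataFrame

    def __post_init__(self):
        t = self.thresholds
        for col in ("low", "mid", "high", "kind"):
            if col not in t.columns:
                raise ValidationError(f"thresholds missing column {col!r}")
        bad = t[(t["low"] >= t["mid"]) | (t["mid"] >= t["high"])]
        if len(bad):
            raise DataError(
                f"thresholds must be strictly increasing; bad: {list(bad.index)}"
            )

    @property
    def principal(self) -> pd.Series:
        t = self.thresholds
        return t["high"].where(t["kind"] == "band1", t["mid"])

    def __contains__(self, nutrient: str) -> bool:
        return nutrient in self.thresholds.index


def effective_density(composition: pd.DataFrame, nutrients=None) -> pd.DataFrame:
    """Per-commodity composite nutrient density per 100 g of raw commodity.

    Combines item weights, edible fractions and household waste:
    ``sum_items w * edible * (1 - waste) * density``.  Item weights must
    sum to 1 within each commodity.
    """
    nutrients = list(nutrients or [n for n in NUTRIENT_UNITS if n in composition.columns])
    wsum = composition.groupby("commodity")["weight"].sum()
    bad = wsum[(wsum - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValidationError(f"item weights must sum to 1 per commodity: {list(bad.index)}")
    for col in ("edible_fraction", "household_waste_fraction"):
        if ((composition[col] < 0) | (composition[col] > 1)).any():
            raise ValidationError(f"{col} must lie in [0, 1]")
    factor = (
        composition["weight"]
        * composition["edible_fraction"]
        * (1.0 - composition["household_waste_fraction"])
    )
    weighted = composition[nutrients].mul(factor, axis=0)
    weighted["commodity"] = composition["commodity"].to_numpy()
    return weighted.groupby("commodity").sum()


def compute_supply(
    balance: pd.DataFrame,
    composition: pd.DataFrame,
    population: float,
) -> pd.Series:
    """Per-capita daily nutrient supply from a food balance.

    ``balance`` must carry a ``food`` column in tonnes; ``composition``
    is the item-level table (columns: commodity, item, weight,
    edible_fraction, household_waste_fraction, nutrient densities per
    100 g edible).  Units follow :data:`NUTRIENT_UNITS` per capita/day.

    Raises
    ------
    CoverageError
        If a commodity with nonzero food supply has no composition rows.
    """
    if population <= 0:
        raise ValidationError("population must be > 0")
    food = balance["food"]
    density = effective_density(composition)
    uncovered = [c for c in food.index[food > 0] if c not in density.index]
    if uncovered:
        raise CoverageError(f"no composition coverage for: {uncovered}")
    density = density.reindex(food.index).fillna(0.0)
    # t -> g is 1e6; densities are per 100 g, hence the 1e4 factor.
    totals = density.mul(food, axis=0).sum(axis=0) * 1e4
    supply = totals / population / 365.0
    supply.name = "supply_per_capita_day"
    return supply


def compute_requirements(
    group_sizes: pd.Series,
    group_references: pd.DataFrame,
    kinds: pd.Series | None = None,
) -> RequirementSet:
    """Population-weighted requirement thresholds.

    ``group_sizes`` gives persons per demographic (age–sex) group;
    ``group_references`` has a (group, nutrient) MultiIndex with
    ascending columns (low, mid, high) per group.  Each population
    threshold is the size-weighted mean of the per-group values.
    ``kinds`` maps nutrient -> {band1, fat, energy} (defaults by name).
    """
    if (group_sizes <= 0).any():
        raise ValidationError("group sizes must be > 0")
    refs = group_references
    bad = refs[(refs["low"] >= refs["mid"]) | (refs["mid"] >= refs["high"])]
    if len(bad):
        raise DataError(
            f"per-group thresholds must be strictly increasing; bad: {list(bad.index)}"
        )
    weights = group_sizes / group_sizes.sum()
    rows = {}
    for nutrient, sub in refs.groupby(level="nutrient", sort=False):
        sub = sub.droplevel("nutrient")
        w = weights.reindex(sub.index)
        if w.isna().any():
            raise DataError(f"missing group sizes for nutrient {nutrient!r}")
        rows[nutrient] = (sub[["low", "mid", "high"]].mul(w, axis=0)).sum(axis=0)
    thresholds = pd.DataFrame.from_dict(rows, orient="index")
    if kinds is None:
        kinds = pd.Series(
            {
                n: ("energy" if n == "energy" else "fat" if n == "fat" else "band1")
                for n in thresholds.index
            }
        )
    thresholds["kind"] = kinds.reindex(thresholds.index)
    return RequirementSet(thresholds)


def _classify_one(supply: float, low: float, mid: float, high: float, kind: str) -> str:
    if kind == "band1":
        if supply < low:
            return "inadequate"
        if supply < mid:
            return "marginal_low"
        if supply < high:
            return "marginal_high"
        return "adequate"
    # fat and energy: below min inadequate, [min, mid) marginal,
    # [mid, max) adequate, at or above max oversupply.
    if supply < low:
        return "inadequate"
    if supply < mid:
        return "marginal_low"
    if supply < high:
        return "adequate"
    return "oversupply"


def classify_adequacy(supply: pd.Series, requirements: RequirementSet) -> pd.DataFrame:
    """Classify per-capita supply against requirement bands.

    Returns a frame indexed by nutrient with columns ``supply``,
    ``ratio_pct`` (100 x supply / principal target) and ``band``.
    Nutrients without a requirement entry are skipped.
    """
    t = requirements.thresholds
    nutrients = [n for n in supply.index if n in t.index]
    principal = requirements.principal
    records = {}
    for n in nutrients:
        s = float(supply[n])
        if s < 0:
            raise ValidationError(f"negative supply for {n!r}")
        band = _classify_one(
            s, t.at[n, "low"], t.at[n, "mid"], t.at[n, "high"], t.at[n, "kind"]
        )
        records[n] = {
            "supply": s,
            "ratio_pct": 100.0 * s / principal[n],
            "band": band,
        }
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "nutrient"
    return out


def meets_requirement(adequacy: pd.DataFrame) -> pd.Series:
    """True where supply meets the principal requirement (band adequate
    or oversupply)."""
    return adequacy["band"].isin(["adequate", "oversupply"])
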