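"""Synthetic baseline and forcing inputs for the full pipeline.

Real-world inputs to this kind of assessment — national food-balance
and yield statistics, bias-corrected climate-model ensembles, UN
demographic projections — are emulated here with the statistical
structure the analysis assumes: multi-commodity baselines spanning
cereal/root/fruit/vegetable/pulse/oil/sugar/animal classes, per-climate-
model yield-impact spreads that widen with climate risk, age–sex
heterogeneity in nutrient requirements, and *designed* adequacy gaps
(nutrients forced below their principal requirement at baseline, fat,
calcium and iron by default) so that downstream adequacy verdicts are
known by construction and the pipeline is testable end to end.

Magnitudes are order-of-magnitude realistic only; no attempt is made to
mimic any particular country.  All draws come from a single RNG keyed
by ``(seed, table name)``, so adding a table never perturbs others and
a fixed seed yields byte-identical bundles.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import food_accounts, nutrition
from .errors import ConfigError
from .livestock_engine import FEED_STREAMS, LIVESTOCK_CATEGORIES, FeedBasket

#: Commodity catalogue: name -> (class, baseline yield t/ha).  Maize and
#: soybean lead so that small bundles always include both.
COMMODITY_CATALOGUE: dict[str, tuple[str, float]] = {
    "maize": ("cereal", 1.8),
    "soybean": ("oil", 1.1),
    "rice": ("cereal", 2.2),
    "wheat": ("cereal", 2.0),
    "sorghum": ("cereal", 1.0),
    "millet": ("cereal", 0.9),
    "cassava": ("root", 8.5),
    "potatoes": ("root", 9.0),
    "sweet_potatoes": ("root", 7.0),
    "bananas": ("fruit", 6.5),
    "mangoes": ("fruit", 7.0),
    "citrus": ("fruit", 8.0),
    "tomatoes": ("vegetable", 10.0),
    "onions": ("vegetable", 12.0),
    "leafy_greens": ("vegetable", 6.0),
    "pulses": ("pulse", 0.9),
    "groundnuts": ("oil", 1.0),
    "sunflower_seed": ("oil", 1.2),
    "sugar_cane": ("sugar", 50.0),
    "plantains": ("fruit", 6.0),
}

#: Class-level nutrient densities per 100 g edible portion (means; the
#: generator jitters them per food item).  Units per NUTRIENT_UNITS.
CLASS_COMPOSITION: dict[str, dict[str, float]] = {
    "cereal": dict(energy=360, protein=9, fat=3, carbohydrate=74, saturated_fat=0.5,
                   fibre=7, calcium=25, zinc=2.0, iron=2.5, vitamin_c=0,
                   thiamin=0.35, riboflavin=0.15, niacin=3.5, folate=25,
                   vitamin_b6=0.3, vitamin_a=10),
    "root": dict(energy=120, protein=1.5, fat=0.3, carbohydrate=28, saturated_fat=0.1,
                 fibre=2.5, calcium=20, zinc=0.4, iron=0.8, vitamin_c=20,
                 thiamin=0.09, riboflavin=0.04, niacin=0.8, folate=20,
                 vitamin_b6=0.2, vitamin_a=5),
    "fruit": dict(energy=60, protein=0.8, fat=0.3, carbohydrate=15, saturated_fat=0.1,
                  fibre=2.5, calcium=15, zinc=0.15, iron=0.4, vitamin_c=40,
                  thiamin=0.04, riboflavin=0.05, niacin=0.6, folate=20,
                  vitamin_b6=0.15, vitamin_a=30),
    "vegetable": dict(energy=35, protein=1.8, fat=0.3, carbohydrate=7, saturated_fat=0.05,
                      fibre=2.0, calcium=50, zinc=0.4, iron=1.2, vitamin_c=30,
                      thiamin=0.07, riboflavin=0.08, niacin=0.8, folate=60,
                      vitamin_b6=0.15, vitamin_a=80),
    "pulse": dict(energy=340, protein=22, fat=1.5, carbohydrate=60, saturated_fat=0.3,
                  fibre=15, calcium=100, zinc=3.0, iron=6.0, vitamin_c=2,
                  thiamin=0.5, riboflavin=0.2, niacin=2.5, folate=400,
                  vitamin_b6=0.4, vitamin_a=2),
    "oil": dict(energy=450, protein=20, fat=25, carbohydrate=25, saturated_fat=4,
                fibre=9, calcium=150, zinc=3.5, iron=4.0, vitamin_c=1,
                thiamin=0.6, riboflavin=0.2, niacin=8.0, folate=150,
                vitamin_b6=0.35, vitamin_a=1),
    "sugar": dict(energy=60, protein=0.3, fat=0.1, carbohydrate=15, saturated_fat=0.0,
                  fibre=1.0, calcium=10, zinc=0.1, iron=0.5, vitamin_c=10,
                  thiamin=0.03, riboflavin=0.02, niacin=0.2, folate=5,
                  vitamin_b6=0.05, vitamin_a=2),
    "bovine_meat": dict(energy=220, protein=20, fat=15, carbohydrate=0, saturated_fat=6,
                        fibre=0, calcium=12, zinc=4.5, iron=2.2, vitamin_c=0,
                        thiamin=0.06, riboflavin=0.2, niacin=5, folate=8,
                        vitamin_b6=0.35, vitamin_a=10),
    "bovine_milk": dict(energy=64, protein=3.3, fat=3.6, carbohydrate=4.7, saturated_fat=2.2,
                        fibre=0, calcium=115, zinc=0.4, iron=0.05, vitamin_c=1,
                        thiamin=0.04, riboflavin=0.18, niacin=0.1, folate=5,
                        vitamin_b6=0.04, vitamin_a=35),
    "sheep_goat_meat": dict(energy=230, protein=18, fat=17, carbohydrate=0, saturated_fat=7,
                            fibre=0, calcium=12, zinc=3.8, iron=2.0, vitamin_c=0,
                            thiamin=0.1, riboflavin=0.22, niacin=5.5, folate=5,
                            vitamin_b6=0.3, vitamin_a=8),
    "sheep_goat_milk": dict(energy=70, protein=3.5, fat=4.2, carbohydrate=4.6, saturated_fat=2.6,
                            fibre=0, calcium=130, zinc=0.45, iron=0.06, vitamin_c=1,
                            thiamin=0.05, riboflavin=0.16, niacin=0.3, folate=6,
                            vitamin_b6=0.05, vitamin_a=40),
    "pig_meat": dict(energy=270, protein=17, fat=22, carbohydrate=0, saturated_fat=8,
                     fibre=0, calcium=8, zinc=2.2, iron=0.9, vitamin_c=0,
                     thiamin=0.7, riboflavin=0.2, niacin=4.5, folate=4,
                     vitamin_b6=0.35, vitamin_a=5),
    "poultry_meat": dict(energy=190, protein=19, fat=12, carbohydrate=0, saturated_fat=3.5,
                         fibre=0, calcium=11, zinc=1.5, iron=1.0, vitamin_c=0,
                         thiamin=0.07, riboflavin=0.15, niacin=7, folate=6,
                         vitamin_b6=0.4, vitamin_a=15),
    "eggs": dict(energy=145, protein=12.5, fat=10, carbohydrate=1, saturated_fat=3.1,
                 fibre=0, calcium=55, zinc=1.3, iron=1.9, vitamin_c=0,
                 thiamin=0.07, riboflavin=0.45, niacin=0.07, folate=50,
                 vitamin_b6=0.17, vitamin_a=160),
}

DEFAULT_DEMO_GROUPS = (
    "children_m", "children_f", "adolescents_m", "adolescents_f",
    "adults_m", "adults_f", "elderly_m", "elderly_f",
)

#: Per-crop extreme-yield shock rates (probability/year).  Maize is more
#: shock-prone than other crops, soybean less so.
DEFAULT_SHOCK_RATES = {"maize": 0.10, "soybean": 0.03}
DEFAULT_SHOCK_RATE = 0.05


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-input generator (defaults are the study
    conditions the pipeline is exercised under)."""

    seed: int = 0
    n_commodities: int = 20
    n_zones: int = 10
    n_climate_models: int = 5
    n_demo_groups: int = 8
    designed_gaps: frozenset[str] = frozenset({"fat", "calcium", "iron"})
    #: Relative yield-trend slope range per crop (fraction of baseline
    #: yield per year); the range reproduces roughly a 100-200% yield
    #: gain over a 50-year horizon under a full trend.
    yield_trend_range: tuple[float, float] = (0.02, 0.04)
    #: Climate-factor dispersion per risk level (log-scale sigma).
    climate_impact_spread: dict[str, float] = field(
        default_factory=lambda: {"RCP2.6": 0.05, "RCP8.5": 0.15}
    )
    shock_rate: float = DEFAULT_SHOCK_RATE
    shock_rate_overrides: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SHOCK_RATES)
    )
    population_baseline: float = 15e6
    population_growth: float = 1.8  # mid-century / baseline population
    designed_gap_ratio: float = 0.75  # baseline supply / principal target
    designed_surplus_ratio: float = 1.30
    energy_ratio: float = 1.15  # between average and maximum requirement
    pasture_yield_t_dm_ha: float = 2.0
    total_arable_ha: float = 4e6
    total_pasture_ha: float = 6e6
    zone_arable_ha: tuple[float, ...] | None = None
    zone_pasture_ha: tuple[float, ...] | None = None
    include_vitamin_a: bool = False

    def __post_init__(self):
        if not 1 <= self.n_commodities <= 96:
            raise ConfigError("n_commodities must be in [1, 96]")
        if self.n_zones < 1 or self.n_climate_models < 1 or self.n_demo_groups < 1:
            raise ConfigError("n_zones, n_climate_models, n_demo_groups must be >= 1")
        tracked = set(nutrition.REQUIRED_NUTRIENTS)
        extra = set(self.designed_gaps) - tracked
        if extra:
            raise ConfigError(f"designed_gaps not among tracked nutrients: {sorted(extra)}")
        if self.zone_arable_ha is not None and len(self.zone_arable_ha) != self.n_zones:
            raise ConfigError("zone_arable_ha length must equal n_zones")

    @property
    def commodities(self) -> list[str]:
        names = list(COMMODITY_CATALOGUE)
        if self.n_commodities <= len(names):
            return names[: self.n_commodities]
        classes = ["cereal", "root", "fruit", "vegetable", "pulse", "oil", "sugar"]
        out = list(names)
        i = 0
        while len(out) < self.n_commodities:
            out.append(f"commodity_{len(out) + 1}_{classes[i % len(classes)]}")
            i += 1
        return out

    def commodity_class(self, name: str) -> str:
        if name in COMMODITY_CATALOGUE:
            return COMMODITY_CATALOGUE[name][0]
        return name.rsplit("_", 1)[-1]

    def base_yield(self, name: str) -> float:
        if name in COMMODITY_CATALOGUE:
            return COMMODITY_CATALOGUE[name][1]
        return {"cereal": 1.5, "root": 8.0, "fruit": 6.5, "vegetable": 9.0,
                "pulse": 0.9, "oil": 1.1, "sugar": 45.0}[self.commodity_class(name)]

    def crop_shock_rate(self, crop: str) -> float:
        return self.shock_rate_overrides.get(crop, self.shock_rate)


def _rng(seed: int, table: str) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, table name)."""
    digest = hashlib.sha256(table.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng([seed, key])


@dataclass
class BaselineBundle:
    """Everything the pipeline needs about a country's baseline."""

    config: GeneratorConfig
    crop_areas: pd.DataFrame        # zones x commodities, ha
    crop_yields: pd.DataFrame       # zones x commodities, t/ha
    yield_history: pd.DataFrame     # years x commodities, national t/ha
    true_slopes: pd.Series          # generating slopes, t/ha/yr
    use_shares: pd.DataFrame        # commodity x (feed, seed, losses)
    trade_imports: pd.Series
    trade_exports: pd.Series
    composition: pd.DataFrame       # item-level food composition
    residue_fractions: pd.Series    # per-crop residue-return feed fraction
    feed_basket: FeedBasket
    livestock_output: pd.Series     # baseline output t per category
    group_sizes_baseline: pd.Series
    group_sizes_2050: pd.Series
    group_references: pd.DataFrame  # (group, nutrient) x (low, mid, high)

    @property
    def commodities(self) -> list[str]:
        return list(self.crop_areas.columns)

    @property
    def all_commodities(self) -> list[str]:
        return self.commodities + list(LIVESTOCK_CATEGORIES)

    @property
    def population_baseline(self) -> float:
        return float(self.group_sizes_baseline.sum())

    @property
    def population_2050(self) -> float:
        return float(self.group_sizes_2050.sum())

    def baseline_crop_production(self) -> pd.Series:
        """National baseline production per crop commodity (t)."""
        return (self.crop_areas * self.crop_yields).sum(axis=0)

    def baseline_production(self) -> pd.Series:
        """Baseline production across crop and livestock commodities."""
        return pd.concat([self.baseline_crop_production(), self.livestock_output])

    def baseline_balance(self) -> pd.DataFrame:
        return food_accounts.build_balance(
            self.baseline_production(),
            self.use_shares,
            imports=self.trade_imports,
            exports=self.trade_exports,
        )

    def requirements(self, year: str = "baseline") -> nutrition.RequirementSet:
        sizes = self.group_sizes_baseline if year == "baseline" else self.group_sizes_2050
        return nutrition.compute_requirements(sizes, self.group_references)


def _generate_crops(config: GeneratorConfig):
    rng = _rng(config.seed, "crops")
    commodities = config.commodities
    nz, nc = config.n_zones, len(commodities)

    if config.zone_arable_ha is not None:
        zone_area = np.asarray(config.zone_arable_ha, dtype=float)
    else:
        w = rng.lognormal(0.0, 0.3, size=nz)
        zone_area = config.total_arable_ha * w / w.sum()

    # Maize-dominated national mix; per-zone Dirichlet draws around it.
    alpha = np.ones(nc)
    for i, c in enumerate(commodities):
        cls = config.commodity_class(c)
        if c == "maize":
            alpha[i] = 10.0
        elif cls == "cereal":
            alpha[i] = 3.0
        elif cls in ("root", "pulse", "oil"):
            alpha[i] = 2.0
    shares = rng.dirichlet(alpha * 2.0, size=nz) if nc > 1 else np.ones((nz, 1))
    areas = shares * zone_area[:, None]

    base = np.array([config.base_yield(c) for c in commodities])
    crop_jit = rng.lognormal(0.0, 0.25, size=nc)
    zone_jit = rng.lognormal(0.0, 0.15, size=(nz, nc))
    yields = base[None, :] * crop_jit[None, :] * zone_jit

    zones = list(range(nz))
    crop_areas = pd.DataFrame(areas, index=zones, columns=commodities)
    crop_yields = pd.DataFrame(yields, index=zones, columns=commodities)

    # Historical national yield series with a linear trend (relative
    # slope per year drawn from the configured range), floored well
    # above zero so early years stay positive.
    hist_rng = _rng(config.seed, "yield_history")
    years = np.arange(1960, 2011)
    nat_yield = (crop_areas * crop_yields).sum(axis=0) / crop_areas.sum(axis=0)
    rel_slopes = hist_rng.uniform(*config.yield_trend_range, size=nc)
    noise = hist_rng.lognormal(0.0, 0.03, size=(len(years), nc))
    ramp = np.maximum(0.15, 1.0 + rel_slopes[None, :] * (years[:, None] - 2000))
    history = pd.DataFrame(
        nat_yield.to_numpy()[None, :] * ramp * noise,
        index=pd.Index(years, name="year"), columns=commodities,
    )
    true_slopes = pd.Series(rel_slopes * nat_yield.to_numpy(), index=commodities)
    return crop_areas, crop_yields, history, true_slopes


def _generate_use_shares(config: GeneratorConfig) -> pd.DataFrame:
    rng = _rng(config.seed, "use_shares")
    rows = {}
    for c in config.commodities:
        cls = config.commodity_class(c)
        feed = 0.15 * rng.uniform(0.7, 1.3) if cls == "cereal" else (
            0.30 * rng.uniform(0.8, 1.2) if c == "soybean" else 0.02 * rng.uniform(0, 1)
        )
        seed = 0.03 if cls in ("cereal", "pulse", "oil") else 0.005
        losses = rng.uniform(0.08, 0.18)
        rows[c] = {"feed": feed, "seed": seed, "losses": losses}
    for cat in LIVESTOCK_CATEGORIES:
        rows[cat] = {"feed": 0.0, "seed": 0.0, "losses": 0.05}
    return pd.DataFrame.from_dict(rows, orient="index")


def _generate_composition(config: GeneratorConfig) -> pd.DataFrame:
    rng = _rng(config.seed, "composition")
    nutrients = [n for n in nutrition.NUTRIENT_UNITS
                 if config.include_vitamin_a or n != "vitamin_a"]
    records = []
    for c in config.commodities + list(LIVESTOCK_CATEGORIES):
        cls = config.commodity_class(c) if c not in CLASS_COMPOSITION else c
        template = CLASS_COMPOSITION[cls]
        weights = rng.dirichlet([2.0, 2.0])
        for i, w in enumerate(weights, start=1):
            jitter = rng.lognormal(0.0, 0.15, size=len(nutrients))
            rec = {
                "commodity": c,
                "item": f"{c}_item{i}",
                "weight": float(w),
                "edible_fraction": float(rng.uniform(0.6, 0.95)),
                "household_waste_fraction": float(rng.uniform(0.05, 0.2)),
            }
            rec.update({n: template.get(n, 0.0) * j for n, j in zip(nutrients, jitter)})
            records.append(rec)
    return pd.DataFrame.from_records(records)


def _generate_trade(config: GeneratorConfig, production: pd.Series):
    rng = _rng(config.seed, "trade")
    n = len(production)
    imports = production * rng.uniform(0.05, 0.20, size=n)
    exports = production * rng.uniform(0.05, 0.20, size=n)
    return imports, exports


def _generate_livestock(config: GeneratorConfig, crop_production: pd.Series,
                        use_shares: pd.DataFrame):
    rng = _rng(config.seed, "livestock")
    commodities = list(crop_production.index)
    residue_fractions = pd.Series(
        {c: (0.3 if config.commodity_class(c) == "cereal" else 0.0) for c in commodities}
    )
    if config.zone_pasture_ha is not None:
        pasture_ha = float(np.sum(config.zone_pasture_ha))
    else:
        pasture_ha = config.total_pasture_ha
    pasture_t = pasture_ha * config.pasture_yield_t_dm_ha
    residues_t = float((crop_production * residue_fractions).sum())
    feedcrops_t = float((crop_production * use_shares["feed"].reindex(commodities)).sum())

    # Ruminants eat pasture and residues; monogastrics eat feed crops.
    ruminants = ("bovine_meat", "bovine_milk", "sheep_goat_meat", "sheep_goat_milk")
    monogastrics = ("pig_meat", "poultry_meat", "eggs")
    shares = pd.DataFrame(0.0, index=list(LIVESTOCK_CATEGORIES), columns=list(FEED_STREAMS))
    shares.loc[list(ruminants), "pasture"] = 0.9 * rng.dirichlet([4, 4, 2, 1])
    shares.loc[list(ruminants), "residues"] = 0.9 * rng.dirichlet([3, 3, 2, 1])
    shares.loc[list(monogastrics), "feedcrops"] = 0.9 * rng.dirichlet([2, 3, 2])
    basket = FeedBasket(
        pasture_t=pasture_t, residues_t=residues_t, feedcrops_t=feedcrops_t,
        allocation_shares=shares,
    )
    efficiency = pd.Series(
        {"bovine_meat": 0.05, "bovine_milk": 0.9, "sheep_goat_meat": 0.05,
         "sheep_goat_milk": 0.7, "pig_meat": 0.25, "poultry_meat": 0.3, "eggs": 0.35}
    ) * rng.lognormal(0.0, 0.1, size=7)
    output = efficiency * basket.allocated_feed()
    output.name = "production_t"
    return basket, output, residue_fractions


def _generate_demography(config: GeneratorConfig):
    rng = _rng(config.seed, "demography")
    if config.n_demo_groups == len(DEFAULT_DEMO_GROUPS):
        groups = list(DEFAULT_DEMO_GROUPS)
    else:
        groups = [f"group_{i + 1}" for i in range(config.n_demo_groups)]
    shares = rng.dirichlet(np.full(len(groups), 4.0)) if len(groups) > 1 else np.ones(1)
    sizes = pd.Series(shares * config.population_baseline, index=groups)
    growth = rng.lognormal(0.0, 0.1, size=len(groups))
    growth *= config.population_growth / float((sizes * growth).sum() / sizes.sum())
    sizes_2050 = sizes * growth
    return sizes, sizes_2050


def _calibrate_references(
    config: GeneratorConfig,
    baseline_supply: pd.Series,
    group_sizes: pd.Series,
) -> pd.DataFrame:
    """Per-group requirement thresholds that realize the designed
    baseline adequacy ratios exactly (population-weighted)."""
    rng = _rng(config.seed, "references")
    groups = list(group_sizes.index)
    weights = (group_sizes / group_sizes.sum()).to_numpy()
    records = {}
    for nutrient in nutrition.REQUIRED_NUTRIENTS:
        if nutrient == "vitamin_a" and not config.include_vitamin_a:
            continue
        supply = float(baseline_supply.get(nutrient, 0.0))
        if supply <= 0:
            raise ConfigError(
                f"cannot design adequacy for {nutrient!r}: zero baseline supply"
            )
        if nutrient in config.designed_gaps:
            ratio = config.designed_gap_ratio
        elif nutrient == "energy":
            ratio = config.energy_ratio
        else:
            ratio = config.designed_surplus_ratio
        principal = supply / ratio
        het = rng.lognormal(0.0, 0.15, size=len(groups))
        het /= float(weights @ het)  # weighted mean exactly 1
        for g, h in zip(groups, het):
            p = principal * h
            if nutrient == "energy":
                low, mid, high = 0.8 * p, p, 1.4 * p
            elif nutrient == "fat":
                low, mid, high = 0.7 * p, p, 1.3 * p
            else:
                low, mid, high = 0.6 * p, 0.8 * p, p
            records[(g, nutrient)] = {"low": low, "mid": mid, "high": high}
    refs = pd.DataFrame.from_dict(records, orient="index")
    refs.index = pd.MultiIndex.from_tuples(refs.index, names=["group", "nutrient"])
    return refs


def generate_baseline(config: GeneratorConfig) -> BaselineBundle:
    """Generate a complete, internally consistent baseline bundle.

    Deterministic under a fixed seed.  Requirement thresholds are
    calibrated so that baseline per-capita supply sits strictly below
    the principal target for every nutrient in ``designed_gaps`` and
    strictly above it for every other tracked nutrient.
    """
    crop_areas, crop_yields, history, true_slopes = _generate_crops(config)
    use_shares = _generate_use_shares(config)
    use_shares = use_shares.loc[[c for c in use_shares.index
                                 if c in config.commodities or c in LIVESTOCK_CATEGORIES]]
    composition = _generate_composition(config)
    crop_production = (crop_areas * crop_yields).sum(axis=0)
    basket, livestock_output, residue_fractions = _generate_livestock(
        config, crop_production, use_shares
    )
    production = pd.concat([crop_production, livestock_output])
    imports, exports = _generate_trade(config, production)
    sizes, sizes_2050 = _generate_demography(config)

    balance = food_accounts.build_balance(
        production, use_shares, imports=imports, exports=exports
    )
    supply = nutrition.compute_supply(balance, composition, float(sizes.sum()))
    references = _calibrate_references(config, supply, sizes)

    return BaselineBundle(
        config=config,
        crop_areas=crop_areas,
        crop_yields=crop_yields,
        yield_history=history,
        true_slopes=true_slopes,
        use_shares=use_shares,
        trade_imports=imports,
        trade_exports=exports,
        composition=composition,
        residue_fractions=residue_fractions,
        feed_basket=basket,
        livestock_output=livestock_output,
        group_sizes_baseline=sizes,
        group_sizes_2050=sizes_2050,
        group_references=references,
    )


#: Public names of the five reported climate models; extra models get
#: generic names.
CLIMATE_MODEL_NAMES = (
    "BCC-CSM1.1m", "GFDL-CM3", "IPSL-CM5A-LR", "MIROC-ESM-CHEM", "MRI-CGCM3",
)


def climate_model_names(n: int) -> list[str]:
    names = list(CLIMATE_MODEL_NAMES[:n])
    names += [f"model_{i + 1}" for i in range(len(names), n)]
    return names


def generate_climate_factors(
    config: GeneratorConfig,
    risk: str,
    commodities: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-(model, zone, crop) multiplicative yield-impact factors.

    Log-normal around (slightly below) 1: log-scale dispersion is the
    configured spread for the risk level, and the median shifts
    downward with the spread, so the high-risk ensemble is both wider
    and more adverse.  A zero spread yields unit factors.

    Returns a frame with (climate_model, zone) MultiIndex and one
    column per commodity.
    """
    if risk not in config.climate_impact_spread:
        raise ConfigError(f"unknown climate risk level {risk!r}")
    sigma = float(config.climate_impact_spread[risk])
    commodities = list(commodities or config.commodities)
    models = climate_model_names(config.n_climate_models)
    rng = _rng(config.seed, f"climate_factors:{risk}")
    nm, nz, nc = len(models), config.n_zones, len(commodities)
    z_model = rng.standard_normal(size=(nm, 1, 1))
    z_local = rng.standard_normal(size=(nm, nz, nc))
    z = 0.8 * z_model + 0.6 * z_local  # unit total variance
    factors = np.exp(sigma * z - 0.5 * sigma)
    index = pd.MultiIndex.from_product([models, range(nz)], names=["climate_model", "zone"])
    return pd.DataFrame(factors.reshape(nm * nz, nc), index=index, columns=commodities)


def generate_shock_series(
    config: GeneratorConfig,
    n_years: int,
    commodities: Sequence[str] | None = None,
    mean_yields: pd.Series | None = None,
) -> pd.DataFrame:
    """Annual per-crop yield series with extreme-shock years.

    Ordinary years vary log-normally (sigma 0.08) around the crop mean;
    shock years, drawn with the per-crop shock rate, fall to 30-45% of
    the mean, i.e. below the half-of-baseline-mean shock threshold.
    """
    if n_years < 1:
        raise ConfigError("n_years must be >= 1")
    commodities = list(commodities or config.commodities)
    rng = _rng(config.seed, "shock_series")
    data = {}
    for c in commodities:
        mean = float(mean_yields[c]) if mean_yields is not None else config.base_yield(c)
        rate = config.crop_shock_rate(c)
        normal = mean * rng.lognormal(0.0, 0.08, size=n_years)
        is_shock = rng.random(n_years) < rate
        shock = mean * rng.uniform(0.30, 0.45, size=n_years)
        data[c] = np.where(is_shock, shock, normal)
    return pd.DataFrame(data, index=pd.RangeIndex(n_years, name="year"))


def with_profile_zones(config: GeneratorConfig, profile) -> GeneratorConfig:
    """Bind the generator's zone structure to a country profile."""
    return replace(
        config,
        n_zones=len(profile.zones),
        zone_arable_ha=tuple(z.arable_ha for z in profile.zones),
        zone_pasture_ha=tuple(z.pasture_ha for z in profile.zones),
    )
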