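"""End-to-end scenario runs: generate → project → account → classify → score.

`run_scenario` evaluates one matrix cell against a baseline bundle:
crop production is projected per climate model, livestock follows the
feed basket, food balances are closed under each trade vignette,
per-capita nutrient supply is classified against the mid-century
requirement set, emissions and shocks are accounted, and the scorecard
rules are applied.  `run_country` and `run_all` wrap this over the
packaged fixtures with per-country synthetic baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    climate_smartness,
    crop_engine,
    food_accounts,
    livestock_engine,
    nutrition,
    scoring_report,
    synthetic_data,
)
from .climate_smartness import EmissionFactors, EmissionsLedger, SocParams
from .crop_engine import AdaptationParams, IrrigationParams
from .scenario_config import (
    CountryProfile,
    ScenarioSet,
    ScenarioSpec,
    enumerate_scenarios,
    load_fixture,
    PACKAGED_COUNTRIES,
)
from .scoring_report import (
    CalibratedStatement,
    ComparisonSummary,
    ScenarioIndicators,
    Scorecard,
    ScoringRules,
)
from .synthetic_data import BaselineBundle, GeneratorConfig

#: Rough mid-baseline national populations (persons) and the ratio of
#: mid-century to baseline population used for the packaged fixtures.
COUNTRY_POPULATION = {
    "Malawi": 11e6,
    "South Africa": 45e6,
    "Tanzania": 34e6,
    "Zambia": 10e6,
}
COUNTRY_POPULATION_GROWTH = {
    "Malawi": 2.0,
    "South Africa": 1.35,
    "Tanzania": 2.0,
    "Zambia": 2.1,
}

SHOCK_SERIES_YEARS = 200


@dataclass
class ScenarioResult:
    """Everything computed for one scenario cell."""

    spec: ScenarioSpec
    production: pd.DataFrame            # tidy (model, commodity, zone) table
    livestock: dict[str, pd.Series]     # model -> category output t
    balances: dict[tuple[str, str], pd.DataFrame]  # (vignette, model) -> balance
    adequacy: pd.DataFrame              # tidy (vignette, model, nutrient) table
    emissions_by_model: dict[str, EmissionsLedger]
    baseline_emissions: EmissionsLedger
    indicators: ScenarioIndicators
    scorecard: Scorecard
    statements: list[CalibratedStatement]


@dataclass
class CountryRun:
    profile: CountryProfile
    bundle: BaselineBundle
    baseline_adequacy: pd.DataFrame
    results: dict[str, ScenarioResult] = field(default_factory=dict)


def baseline_adequacy(bundle: BaselineBundle) -> pd.DataFrame:
    """Adequacy of the baseline food supply against baseline requirements."""
    balance = bundle.baseline_balance()
    supply = nutrition.compute_supply(
        balance, bundle.composition, bundle.population_baseline
    )
    return nutrition.classify_adequacy(supply, bundle.requirements("baseline"))


def run_scenario(
    spec: ScenarioSpec,
    profile: CountryProfile,
    bundle: BaselineBundle,
    *,
    vignettes: tuple[str, ...] = food_accounts.VIGNETTES,
    rules: ScoringRules | None = None,
    adaptation: AdaptationParams = AdaptationParams(),
    irrigation: IrrigationParams = IrrigationParams(),
    emission_factors: EmissionFactors | None = None,
    soc_params: SocParams = SocParams(),
    baseline_adequacy_df: pd.DataFrame | None = None,
) -> ScenarioResult:
    """Run the full chain for one scenario cell."""
    rules = rules or ScoringRules.load()
    emission_factors = emission_factors or EmissionFactors()

    slopes = crop_engine.fit_trend_slopes(bundle.yield_history)
    factors = synthetic_data.generate_climate_factors(
        bundle.config, spec.climate_risk, bundle.commodities
    )
    production = crop_engine.project_production(
        spec, profile, bundle.crop_areas, bundle.crop_yields, slopes,
        climate_factors=factors, adaptation=adaptation, irrigation=irrigation,
    )
    national = crop_engine.national_production(production)

    feed_ratios = livestock_engine.fit_feed_ratios(
        bundle.feed_basket, bundle.livestock_output
    )
    trade_ratios = food_accounts.fit_trade_ratios(
        bundle.baseline_production(), bundle.trade_imports, bundle.trade_exports
    )
    requirements_2050 = bundle.requirements("2050")
    # "Clearly below requirement" line as % of the principal target:
    # the EAR for band-1 nutrients, the minimum intake for fat/energy
    # (whose principal IS the mid threshold).
    t2050 = requirements_2050.thresholds
    ear_ratio_pct = 100.0 * t2050["mid"].where(
        t2050["kind"] == "band1", t2050["low"]
    ) / requirements_2050.principal

    baseline_production = bundle.baseline_production()
    baseline_total = float(baseline_production.sum())
    baseline_crop = bundle.baseline_crop_production()
    baseline_ledger = climate_smartness.compute_emissions(
        baseline_crop, bundle.livestock_output, 0.0, emission_factors, soc_params
    )

    expanded_ha = (
        max(spec.arable_area_change, 0.0) * profile.arable_ha
        + max(spec.pasture_area_change, 0.0) * profile.pasture_ha
    )

    livestock: dict[str, pd.Series] = {}
    balances: dict[tuple[str, str], pd.DataFrame] = {}
    adequacy_rows = []
    emissions_by_model: dict[str, EmissionsLedger] = {}
    deltas = {}

    for model in national.index:
        crop_nat = national.loc[model].reindex(bundle.commodities).fillna(0.0)
        future_basket = livestock_engine.FeedBasket(
            pasture_t=bundle.feed_basket.pasture_t,
            residues_t=livestock_engine.residue_supply(crop_nat, bundle.residue_fractions),
            feedcrops_t=float(
                (crop_nat * bundle.use_shares["feed"].reindex(crop_nat.index)).sum()
            ),
            allocation_shares=bundle.feed_basket.allocation_shares,
        )
        stock = livestock_engine.project_livestock(spec, future_basket, feed_ratios)
        livestock[model] = stock

        production_all = pd.concat([crop_nat, stock])
        deltas[model] = float(production_all.sum()) / baseline_total - 1.0

        emissions_by_model[model] = climate_smartness.compute_emissions(
            crop_nat, stock, expanded_ha, emission_factors, soc_params
        )

        base_balance = food_accounts.build_balance(production_all, bundle.use_shares)
        for vignette_kind in vignettes:
            vignette = food_accounts.vignette_from_spec(
                vignette_kind, spec.trade_vignette_params
            )
            balance = food_accounts.apply_trade_vignette(
                base_balance, vignette, trade_ratios
            )
            balances[(vignette_kind, model)] = balance
            supply = nutrition.compute_supply(
                balance, bundle.composition, bundle.population_2050
            )
            adequacy = nutrition.classify_adequacy(supply, requirements_2050)
            adequacy = adequacy.reset_index()
            adequacy.insert(0, "climate_model", model)
            adequacy.insert(0, "vignette", vignette_kind)
            adequacy_rows.append(adequacy)

    adequacy_df = pd.concat(adequacy_rows, ignore_index=True)

    if baseline_adequacy_df is None:
        baseline_adequacy_df = baseline_adequacy(bundle)
    shock_series = synthetic_data.generate_shock_series(
        bundle.config, SHOCK_SERIES_YEARS, bundle.commodities
    )
    shock_summaries = [
        climate_smartness.count_yield_shocks(
            shock_series[c], float(shock_series[c].mean()), crop=c
        )
        for c in shock_series.columns
    ]

    indicators = ScenarioIndicators(
        scenario_id=spec.scenario_id,
        country=spec.country,
        transformation=spec.transformation,
        climate_risk=spec.climate_risk,
        production_delta_by_model=pd.Series(deltas),
        adequacy=adequacy_df,
        ear_ratio_pct=ear_ratio_pct,
        emissions_by_model=emissions_by_model,
        baseline_emissions=baseline_ledger,
        baseline_mean_ratio_pct=float(baseline_adequacy_df["ratio_pct"].mean()),
        shock_summaries=shock_summaries,
    )
    scorecard = scoring_report.score_scenario(indicators, rules)
    statements = scoring_report.generate_statements(scorecard, indicators, rules)

    return ScenarioResult(
        spec=spec,
        production=production,
        livestock=livestock,
        balances=balances,
        adequacy=adequacy_df,
        emissions_by_model=emissions_by_model,
        baseline_emissions=baseline_ledger,
        indicators=indicators,
        scorecard=scorecard,
        statements=statements,
    )


def country_seed(seed: int, country: str) -> int:
    """Stable per-country sub-seed below 2^31."""
    idx = PACKAGED_COUNTRIES.index(country) if country in PACKAGED_COUNTRIES else 7
    return (seed * 1000003 + idx * 7919) % (2**31)


def country_config(country: str, seed: int, profile: CountryProfile) -> GeneratorConfig:
    """Generator configuration bound to a packaged country fixture."""
    config = GeneratorConfig(
        seed=country_seed(seed, country),
        population_baseline=COUNTRY_POPULATION.get(country, 15e6),
        population_growth=COUNTRY_POPULATION_GROWTH.get(country, 1.8),
    )
    return synthetic_data.with_profile_zones(config, profile)


def run_country(
    country: str,
    seed: int = 0,
    *,
    rules: ScoringRules | None = None,
    vignettes: tuple[str, ...] = food_accounts.VIGNETTES,
) -> CountryRun:
    """Generate a country baseline and run its four matrix cells."""
    profile, cells = load_fixture(country)
    config = country_config(country, seed, profile)
    bundle = synthetic_data.generate_baseline(config)
    scenario_set = enumerate_scenarios([profile], {profile.name: cells})
    base_adequacy = baseline_adequacy(bundle)
    run = CountryRun(profile=profile, bundle=bundle, baseline_adequacy=base_adequacy)
    for spec in scenario_set:
        run.results[spec.cell] = run_scenario(
            spec, profile, bundle,
            rules=rules, vignettes=vignettes,
            baseline_adequacy_df=base_adequacy,
        )
    return run


@dataclass
class AssessmentRun:
    countries: dict[str, CountryRun]
    comparison: ComparisonSummary

    @property
    def scorecards(self) -> list[Scorecard]:
        return [
            r.scorecard
            for run in self.countries.values()
            for r in run.results.values()
        ]

    @property
    def results(self) -> list[ScenarioResult]:
        return [r for run in self.countries.values() for r in run.results.values()]


def run_all(
    seed: int = 0,
    countries: tuple[str, ...] = PACKAGED_COUNTRIES,
    *,
    rules: ScoringRules | None = None,
    vignettes: tuple[str, ...] = food_accounts.VIGNETTES,
) -> AssessmentRun:
    """Run every scenario cell of the packaged fixtures."""
    runs = {
        c: run_country(c, seed, rules=rules, vignettes=vignettes) for c in countries
    }
    scorecards = [r.scorecard for run in runs.values() for r in run.results.values()]
    comparison = scoring_report.compare_scenarios(scorecards)
    return AssessmentRun(countries=runs, comparison=comparison)
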