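"""Yield projection and the production-maximizing land allocation."""

import numpy as np
import pandas as pd
import pytest

from nutriscen.crop_engine import (
    AdaptationParams,
    allocate_crops,
    apply_adaptation,
    apply_yield_trend,
    diversification_bounds,
    fit_trend_slopes,
    national_production,
    project_production,
)
from nutriscen.errors import AllocationInfeasibleError, ValidationError
from nutriscen.scenario_config import CountryProfile, LandZone, ScenarioSpec

from conftest import as_share_bounds, brute_force_allocation, random_allocation_instance

IDENTITY_ADAPTATION = AdaptationParams(0.0, 0.0, 0.0)


class TestYieldTrend:
    @pytest.mark.parametrize(
        "mode,expected", [("full", 2.0), ("half", 1.5), ("none", 1.0)]
    )
    def test_linear_extrapolation_modes(self, mode, expected):
        assert apply_yield_trend(1.0, 0.02, mode, 50) == pytest.approx(expected)

    def test_negative_trend_floors_at_zero(self):
        assert apply_yield_trend(1.0, -0.05, "full", 50) == 0.0

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValidationError):
            apply_yield_trend(-1.0, 0.02, "full", 50)

    def test_ols_recovers_linear_slope(self):
        years = np.arange(1960, 2011)
        history = pd.DataFrame(
            {"a": 1.0 + 0.03 * (years - 1960), "b": 2.0 - 0.01 * (years - 1960)},
            index=pd.Index(years, name="year"),
        )
        slopes = fit_trend_slopes(history)
        assert slopes["a"] == pytest.approx(0.03)
        assert slopes["b"] == pytest.approx(-0.01)


class TestAdaptation:
    def test_zero_uplift_identity(self):
        assert apply_adaptation(1.7, "transformative", IDENTITY_ADAPTATION) == pytest.approx(1.7)

    def test_transformative_uplift_arithmetic(self):
        params = AdaptationParams(0.0, 0.1, 0.0)
        assert apply_adaptation(2.0, "transformative", params) == pytest.approx(2.2)

    def test_autonomous_keeps_growing_season_penalty(self):
        params = AdaptationParams(0.05, 0.1, 0.04)
        assert apply_adaptation(1.0, "autonomous", params) == pytest.approx(1.05 * 0.96)
        assert apply_adaptation(1.0, "transformative", params) == pytest.approx(1.1)

    def test_autonomous_above_transformative_rejected(self):
        with pytest.raises(ValidationError):
            AdaptationParams(0.2, 0.1)


class TestAllocation:
    def test_two_zone_comparative_advantage(self):
        yields = pd.DataFrame([[2.0, 1.0], [1.0, 3.0]], index=["z1", "z2"],
                              columns=["crop1", "crop2"])
        areas = pd.Series([10.0, 10.0], index=["z1", "z2"])
        plan = allocate_crops(yields, areas, {"crop1": (0, 0.5), "crop2": (0, 0.5)})
        assert plan.objective == pytest.approx(50.0, rel=1e-6)
        assert plan.area.at["z1", "crop1"] == pytest.approx(10.0, rel=1e-6)
        assert plan.area.at["z2", "crop2"] == pytest.approx(10.0, rel=1e-6)

    def test_single_commodity_takes_everything(self):
        yields = pd.DataFrame({"only": [2.0, 3.0]}, index=["z1", "z2"])
        areas = pd.Series([5.0, 7.0], index=["z1", "z2"])
        plan = allocate_crops(yields, areas)
        assert plan.objective == pytest.approx(5 * 2 + 7 * 3)

    def test_maize_cap_is_respected(self):
        yields = pd.DataFrame(
            [[3.0, 1.0], [3.0, 1.0]], index=["z1", "z2"], columns=["maize", "beans"]
        )
        areas = pd.Series([10.0, 10.0], index=["z1", "z2"])
        plan = allocate_crops(yields, areas, {"maize": (0.0, 0.3)})
        maize_share = plan.area["maize"].sum() / areas.sum()
        assert maize_share <= 0.3 + 1e-9

    def test_infeasible_min_shares_raise(self):
        yields = pd.DataFrame([[1.0, 1.0]], index=["z"], columns=["a", "b"])
        areas = pd.Series([1.0], index=["z"])
        with pytest.raises(AllocationInfeasibleError):
            allocate_crops(yields, areas, {"a": (0.7, 1.0), "b": (0.6, 1.0)})

    def test_protected_zone_receives_no_area(self):
        yields = pd.DataFrame([[5.0], [9.0]], index=["open", "protected"], columns=["c"])
        areas = pd.Series([4.0, 0.0], index=["open", "protected"])
        plan = allocate_crops(yields, areas)
        assert plan.area.at["protected", "c"] == 0.0

    def test_lp_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(30):
            yields, areas, mins, maxs = random_allocation_instance(rng)
            total = int(areas.sum())
            oracle = brute_force_allocation(yields, areas, mins, maxs)
            frame = pd.DataFrame(yields, columns=[f"crop{j}" for j in range(yields.shape[1])])
            plan = allocate_crops(
                frame, pd.Series(areas.astype(float)),
                as_share_bounds(mins, maxs, total),
            )
            assert plan.objective == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_yield_increase_never_decreases_objective(self, rng):
        for _ in range(20):
            yields, areas, mins, maxs = random_allocation_instance(rng)
            total = int(areas.sum())
            bounds = as_share_bounds(mins, maxs, total)
            frame = pd.DataFrame(yields, columns=list(bounds))
            base = allocate_crops(frame, pd.Series(areas.astype(float)), bounds).objective
            bumped = frame + rng.uniform(0, 1.0, size=frame.shape)
            more = allocate_crops(bumped, pd.Series(areas.astype(float)), bounds).objective
            assert more >= base - 1e-9 * max(base, 1.0)


@pytest.fixture
def toy_profile():
    return CountryProfile(
        name="Toyland",
        zones=(
            LandZone(arable_ha=10.0, pasture_ha=0.0, expandable_ha=10.0),
            LandZone(arable_ha=10.0, pasture_ha=0.0, expandable_ha=0.0, protected=True),
        ),
    )


@pytest.fixture
def toy_inputs():
    zones = [0, 1]
    areas = pd.DataFrame({"maize": [6.0, 6.0], "beans": [4.0, 4.0]}, index=zones)
    yields = pd.DataFrame({"maize": [2.0, 2.0], "beans": [1.0, 1.5]}, index=zones)
    slopes = pd.Series({"maize": 0.0, "beans": 0.0})
    return areas, yields, slopes


class TestProjectProduction:
    def test_identity_scenario_reproduces_baseline(self, toy_profile, toy_inputs):
        areas, yields, slopes = toy_inputs
        spec = ScenarioSpec(country="Toyland", transformation="LT",
                            climate_risk="RCP2.6", yield_trend_mode="none")
        table = project_production(
            spec, toy_profile, areas, yields, slopes, adaptation=IDENTITY_ADAPTATION
        )
        national = national_production(table).loc["nominal"]
        baseline = (areas * yields).sum(axis=0)
        pd.testing.assert_series_equal(
            national, baseline, check_names=False, rtol=1e-9
        )

    def test_production_is_linear_in_yields(self, toy_profile, toy_inputs):
        areas, yields, slopes = toy_inputs
        spec = ScenarioSpec(country="Toyland", transformation="LT",
                            climate_risk="RCP2.6", yield_trend_mode="none")
        one = national_production(project_production(
            spec, toy_profile, areas, yields, slopes, adaptation=IDENTITY_ADAPTATION
        )).loc["nominal"]
        two = national_production(project_production(
            spec, toy_profile, areas, 2 * yields, slopes, adaptation=IDENTITY_ADAPTATION
        )).loc["nominal"]
        pd.testing.assert_series_equal(two, 2 * one, rtol=1e-9)

    def test_optimized_allocation_beats_baseline_shares(self, toy_profile, toy_inputs):
        areas, yields, slopes = toy_inputs
        lt = ScenarioSpec(country="Toyland", transformation="LT",
                          climate_risk="RCP2.6", yield_trend_mode="none")
        ht = ScenarioSpec(country="Toyland", transformation="HT",
                          climate_risk="RCP2.6", yield_trend_mode="none",
                          optimize_allocation=True)
        base = national_production(project_production(
            lt, toy_profile, areas, yields, slopes, adaptation=IDENTITY_ADAPTATION
        )).loc["nominal"].sum()
        optimized = national_production(project_production(
            ht, toy_profile, areas, yields, slopes, adaptation=IDENTITY_ADAPTATION
        )).loc["nominal"].sum()
        assert optimized >= base - 1e-9

    def test_expansion_never_uses_protected_land(self, toy_profile, toy_inputs):
        areas, yields, slopes = toy_inputs
        spec = ScenarioSpec(country="Toyland", transformation="HT",
                            climate_risk="RCP2.6", yield_trend_mode="none",
                            arable_area_change=0.5, optimize_allocation=True)
        table = project_production(
            spec, toy_profile, areas, yields, slopes, adaptation=IDENTITY_ADAPTATION
        )
        by_zone = table.groupby("zone")["area_ha"].sum()
        assert by_zone[1] <= 10.0 + 1e-9  # protected zone never grows
        assert by_zone[0] == pytest.approx(20.0)  # all expansion in open zone


def test_diversification_bounds_modes():
    spec_inc = ScenarioSpec(country="X", transformation="HT", climate_risk="RCP2.6",
                            diversification="increase", maize_share_bound=0.3)
    spec_dec = ScenarioSpec(country="X", transformation="HT", climate_risk="RCP2.6",
                            diversification="decrease", maize_share_bound=0.5)
    shares = pd.Series({"maize": 0.6, "beans": 0.4})
    inc = diversification_bounds(spec_inc, ["maize", "beans"], shares)
    assert inc["maize"][1] == 0.3 and inc["beans"][1] == 0.3
    dec = diversification_bounds(spec_dec, ["maize", "beans"], shares)
    assert dec["maize"][0] == 0.5
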