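"""Nutrient supply accounting and adequacy-band classification."""

import numpy as np
import pandas as pd
import pytest

from nutriscen.errors import CoverageError, DataError, ValidationError
from nutriscen.nutrition import (
    RequirementSet,
    classify_adequacy,
    compute_requirements,
    compute_supply,
    effective_density,
    meets_requirement,
)


def make_composition(rows):
    defaults = {"weight": 1.0, "edible_fraction": 1.0, "household_waste_fraction": 0.0,
                "energy": 0.0, "iron": 0.0}
    return pd.DataFrame([{**defaults, **r} for r in rows])


def balance_with_food(food: dict) -> pd.DataFrame:
    idx = list(food)
    zero = pd.Series(0.0, index=idx)
    return pd.DataFrame(
        {"production": pd.Series(food), "imports": zero, "exports": zero,
         "stock_change": zero, "feed": zero, "seed": zero, "losses": zero,
         "food": pd.Series(food)}
    )


def band1_requirements(nutrient="iron", rni=10.0):
    thresholds = pd.DataFrame(
        {"low": [0.6 * rni], "mid": [0.8 * rni], "high": [rni], "kind": ["band1"]},
        index=[nutrient],
    )
    return RequirementSet(thresholds)


class TestSupply:
    def test_edible_and_waste_fractions_discount_tonnage(self):
        comp = make_composition([
            {"commodity": "c", "item": "i", "edible_fraction": 0.8,
             "household_waste_fraction": 0.1, "energy": 100.0}
        ])
        # 1 t food -> 1e4 * 100 kcal * 0.72 discount
        supply = compute_supply(balance_with_food({"c": 1.0}), comp, population=1.0)
        assert supply["energy"] == pytest.approx(0.8 * 0.9 * 1e4 * 100 / 365)

    def test_item_weights_form_convex_combination(self):
        comp = make_composition([
            {"commodity": "c", "item": "i1", "weight": 0.5, "energy": 100.0},
            {"commodity": "c", "item": "i2", "weight": 0.5, "energy": 200.0},
        ])
        density = effective_density(comp)
        assert density.at["c", "energy"] == pytest.approx(150.0)

    def test_doubling_population_halves_per_capita_supply(self):
        comp = make_composition([{"commodity": "c", "item": "i", "energy": 50.0}])
        balance = balance_with_food({"c": 10.0})
        one = compute_supply(balance, comp, population=1e6)
        two = compute_supply(balance, comp, population=2e6)
        pd.testing.assert_series_equal(two, one / 2)

    def test_supply_is_linear_in_food_column(self):
        comp = make_composition([
            {"commodity": "a", "item": "i", "energy": 50.0, "iron": 1.0},
            {"commodity": "b", "item": "j", "energy": 80.0},
        ])
        s_a = compute_supply(balance_with_food({"a": 3.0, "b": 0.0}), comp, 100.0)
        s_b = compute_supply(balance_with_food({"a": 0.0, "b": 5.0}), comp, 100.0)
        s_ab = compute_supply(balance_with_food({"a": 3.0, "b": 5.0}), comp, 100.0)
        pd.testing.assert_series_equal(s_ab, s_a + s_b)

    def test_zero_density_filler_changes_nothing(self):
        comp = make_composition([
            {"commodity": "a", "item": "i", "energy": 50.0},
            {"commodity": "filler", "item": "f", "energy": 0.0},
        ])
        without = compute_supply(balance_with_food({"a": 3.0, "filler": 0.0}), comp, 10.0)
        with_filler = compute_supply(balance_with_food({"a": 3.0, "filler": 99.0}), comp, 10.0)
        pd.testing.assert_series_equal(without, with_filler)

    def test_uncovered_commodity_raises_coverage_error(self):
        comp = make_composition([{"commodity": "a", "item": "i"}])
        with pytest.raises(CoverageError, match="mystery"):
            compute_supply(balance_with_food({"a": 1.0, "mystery": 5.0}), comp, 10.0)

    def test_bad_item_weights_rejected(self):
        comp = make_composition([
            {"commodity": "c", "item": "i1", "weight": 0.6},
            {"commodity": "c", "item": "i2", "weight": 0.6},
        ])
        with pytest.raises(ValidationError, match="weights"):
            compute_supply(balance_with_food({"c": 1.0}), comp, 10.0)


class TestRequirements:
    def refs(self, values):
        rows = {}
        for group, rni in values.items():
            rows[(group, "iron")] = {"low": 0.6 * rni, "mid": 0.8 * rni, "high": rni}
        refs = pd.DataFrame.from_dict(rows, orient="index")
        refs.index = pd.MultiIndex.from_tuples(refs.index, names=["group", "nutrient"])
        return refs

    def test_two_equal_groups_average(self):
        reqs = compute_requirements(
            pd.Series({"g1": 100.0, "g2": 100.0}), self.refs({"g1": 20.0, "g2": 28.0})
        )
        assert reqs.thresholds.at["iron", "high"] == pytest.approx(24.0)

    def test_single_group_identity(self):
        reqs = compute_requirements(pd.Series({"g": 5.0}), self.refs({"g": 18.0}))
        assert reqs.thresholds.at["iron", "high"] == pytest.approx(18.0)

    def test_weight_shift_toward_high_requirement_group_raises_threshold(self):
        refs = self.refs({"lo": 20.0, "hi": 28.0})
        even = compute_requirements(pd.Series({"lo": 100.0, "hi": 100.0}), refs)
        skewed = compute_requirements(pd.Series({"lo": 50.0, "hi": 150.0}), refs)
        assert (
            skewed.thresholds.at["iron", "high"] > even.thresholds.at["iron", "high"]
        )

    def test_non_increasing_group_thresholds_rejected(self):
        refs = self.refs({"g": 20.0})
        refs.loc[("g", "iron"), "mid"] = 25.0  # above the RNI
        with pytest.raises(DataError):
            compute_requirements(pd.Series({"g": 1.0}), refs)


class TestClassification:
    def test_supply_at_weighted_requirement_is_exactly_100pct_adequate(self):
        reqs = compute_requirements(
            pd.Series({"g1": 100.0, "g2": 100.0}),
            TestRequirements().refs({"g1": 20.0, "g2": 28.0}),
        )
        result = classify_adequacy(pd.Series({"iron": 24.0}), reqs)
        assert result.at["iron", "ratio_pct"] == pytest.approx(100.0)
        assert result.at["iron", "band"] == "adequate"

    def test_zero_supply_is_inadequate_at_zero_pct(self):
        result = classify_adequacy(pd.Series({"iron": 0.0}), band1_requirements())
        assert result.at["iron", "ratio_pct"] == 0.0
        assert result.at["iron", "band"] == "inadequate"

    @pytest.mark.parametrize(
        "supply,band",
        [(5.9, "inadequate"), (6.0, "marginal_low"), (8.0, "marginal_high"),
         (10.0, "adequate"), (15.0, "adequate")],
    )
    def test_band1_boundaries_are_lower_closed(self, supply, band):
        result = classify_adequacy(pd.Series({"iron": supply}), band1_requirements(rni=10.0))
        assert result.at["iron", "band"] == band

    def test_energy_oversupply_above_maximum_requirement(self):
        thresholds = pd.DataFrame(
            {"low": [1600.0], "mid": [2000.0], "high": [2800.0], "kind": ["energy"]},
            index=["energy"],
        )
        reqs = RequirementSet(thresholds)
        over = classify_adequacy(pd.Series({"energy": 5000.0}), reqs)
        assert over.at["energy", "band"] == "oversupply"
        assert over.at["energy", "ratio_pct"] == pytest.approx(250.0)
        ok = classify_adequacy(pd.Series({"energy": 2100.0}), reqs)
        assert ok.at["energy", "band"] == "adequate"

    def test_fat_below_minimum_is_inadequate(self):
        thresholds = pd.DataFrame(
            {"low": [40.0], "mid": [60.0], "high": [80.0], "kind": ["fat"]},
            index=["fat"],
        )
        reqs = RequirementSet(thresholds)
        assert classify_adequacy(pd.Series({"fat": 30.0}), reqs).at["fat", "band"] == "inadequate"
        assert classify_adequacy(pd.Series({"fat": 90.0}), reqs).at["fat", "band"] == "oversupply"

    def test_increasing_supply_never_lowers_the_band(self):
        reqs = band1_requirements(rni=10.0)
        order = {"inadequate": 0, "marginal_low": 1, "marginal_high": 2, "adequate": 3}
        bands = [
            classify_adequacy(pd.Series({"iron": s}), reqs).at["iron", "band"]
            for s in np.linspace(0, 20, 81)
        ]
        ranks = [order[b] for b in bands]
        assert ranks == sorted(ranks)

    def test_meets_requirement_helper(self):
        reqs = band1_requirements(rni=10.0)
        result = classify_adequacy(pd.Series({"iron": 12.0}), reqs)
        assert meets_requirement(result).all()
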