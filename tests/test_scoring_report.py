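"""Scorecard rules, calibrated statements and cross-scenario comparison."""

import numpy as np
import pandas as pd
import pytest

from nutriscen.climate_smartness import EmissionsLedger
from nutriscen.errors import ScoringError, ValidationError
from nutriscen.scoring_report import (
    PILLARS,
    CalibratedStatement,
    ScenarioIndicators,
    Scorecard,
    ScoringRules,
    compare_scenarios,
    generate_statements,
    render_markdown,
    score_scenario,
)

MODELS = [f"m{i}" for i in range(5)]
NUTRIENTS = ["energy", "protein", "iron"]


def make_indicators(
    ratios_by_vignette: dict[str, float],
    deltas=0.2,
    net_change=100.0,
    scenario_id="X:HT-RCP2.6",
) -> ScenarioIndicators:
    """Uniform-ratio indicators across models; one ratio per vignette."""
    rows = []
    for vignette, ratio in ratios_by_vignette.items():
        for model in MODELS:
            for n in NUTRIENTS:
                rows.append(
                    {"vignette": vignette, "climate_model": model, "nutrient": n,
                     "ratio_pct": ratio, "band": "adequate"}
                )
    base = EmissionsLedger(1000.0, 500.0, 0.0, 100.0)
    emissions = {
        m: EmissionsLedger(1000.0 + net_change, 500.0, 0.0, 100.0) for m in MODELS
    }
    deltas = pd.Series(
        deltas if np.ndim(deltas) else [deltas] * len(MODELS), index=MODELS
    )
    country, cell = scenario_id.split(":")
    t, r = cell.split("-", 1)
    return ScenarioIndicators(
        scenario_id=scenario_id, country=country, transformation=t, climate_risk=r,
        production_delta_by_model=deltas,
        adequacy=pd.DataFrame(rows),
        ear_ratio_pct=pd.Series(80.0, index=NUTRIENTS),
        emissions_by_model=emissions,
        baseline_emissions=base,
        baseline_mean_ratio_pct=90.0,
    )


class TestScoring:
    def test_all_requirements_met_everywhere_is_blue_with_star(self):
        ind = make_indicators({"self_sufficiency": 120.0, "business_as_usual": 130.0})
        card = score_scenario(ind)
        assert card.verdicts["nutrition_security"] == "blue"
        assert card.stars["nutrition_security"]

    def test_met_in_one_vignette_only_is_blue_without_star(self):
        ind = make_indicators({"self_sufficiency": 90.0, "business_as_usual": 130.0})
        card = score_scenario(ind)
        assert card.verdicts["nutrition_security"] == "blue"
        assert not card.stars["nutrition_security"]

    def test_below_ear_in_every_vignette_is_red(self):
        ind = make_indicators({"self_sufficiency": 70.0, "business_as_usual": 75.0})
        assert score_scenario(ind).verdicts["nutrition_security"] == "red"

    def test_between_ear_and_target_is_amber(self):
        ind = make_indicators({"self_sufficiency": 85.0, "business_as_usual": 95.0})
        assert score_scenario(ind).verdicts["nutrition_security"] == "amber"

    def test_productivity_thresholds(self):
        blue = score_scenario(make_indicators({"v": 120.0}, deltas=0.15))
        red = score_scenario(make_indicators({"v": 120.0}, deltas=-0.10))
        amber = score_scenario(make_indicators({"v": 120.0}, deltas=0.02))
        assert blue.verdicts["productivity"] == "blue"
        assert red.verdicts["productivity"] == "red"
        assert amber.verdicts["productivity"] == "amber"

    def test_mitigation_blue_when_net_falls(self):
        falling = score_scenario(make_indicators({"v": 120.0}, net_change=-50.0))
        rising = score_scenario(make_indicators({"v": 120.0}, net_change=500.0))
        assert falling.verdicts["mitigation"] == "blue"
        assert rising.verdicts["mitigation"] == "red"

    def test_missing_indicators_raise(self):
        ind = make_indicators({"v": 120.0})
        ind.adequacy = ind.adequacy.iloc[0:0]
        with pytest.raises(ScoringError):
            score_scenario(ind)

    def test_scoring_is_deterministic(self):
        ind = make_indicators({"v": 97.0}, deltas=[0.1, 0.2, -0.1, 0.05, 0.3])
        assert score_scenario(ind) == score_scenario(ind)


class TestStructuralInvariants:
    def test_star_requires_blue(self):
        with pytest.raises(ValidationError, match="star"):
            Scorecard(
                scenario_id="s", country="c", transformation="HT",
                climate_risk="RCP2.6",
                verdicts={p: "amber" for p in PILLARS},
                stars={p: (p == "productivity") for p in PILLARS},
            )

    def test_all_pillars_required(self):
        with pytest.raises(ValidationError):
            Scorecard(
                scenario_id="s", country="c", transformation="HT",
                climate_risk="RCP2.6",
                verdicts={"productivity": "blue"}, stars={},
            )

    def test_statement_needs_an_indicator(self):
        with pytest.raises(ValidationError):
            CalibratedStatement(pillar="p", text="t", confidence="high", indicators=())


class TestStatements:
    def test_one_statement_per_pillar_with_verdict_keyword(self):
        ind = make_indicators({"business_as_usual": 120.0})
        card = score_scenario(ind)
        statements = generate_statements(card, ind)
        assert [s.pillar for s in statements] == list(PILLARS)
        for s in statements:
            assert card.verdicts[s.pillar] in s.text

    @pytest.mark.parametrize(
        "deltas,expected",
        [([0.1, 0.2, 0.3, 0.1, 0.2], "high"),
         ([0.1, 0.2, 0.3, 0.1, -0.2], "medium"),
         ([0.1, 0.2, -0.3, 0.1, -0.2], "low")],
    )
    def test_confidence_tracks_cross_model_sign_agreement(self, deltas, expected):
        ind = make_indicators({"business_as_usual": 120.0}, deltas=deltas)
        card = score_scenario(ind)
        statements = generate_statements(card, ind)
        productivity = next(s for s in statements if s.pillar == "productivity")
        assert productivity.confidence == expected

    def test_markdown_report_mentions_every_pillar(self):
        ind = make_indicators({"business_as_usual": 120.0})
        card = score_scenario(ind)
        text = render_markdown(card, generate_statements(card, ind))
        for p in PILLARS:
            assert p in text


class TestComparison:
    def card(self, country, t, r, nutrition="blue"):
        verdicts = {p: "amber" for p in PILLARS}
        verdicts["nutrition_security"] = nutrition
        return Scorecard(
            scenario_id=f"{country}:{t}-{r}", country=country,
            transformation=t, climate_risk=r, verdicts=verdicts,
            stars={p: False for p in PILLARS},
        )

    def full_matrix(self, country, ht="blue", lt="red"):
        return [
            self.card(country, "LT", "RCP2.6", lt),
            self.card(country, "LT", "RCP8.5", lt),
            self.card(country, "HT", "RCP2.6", ht),
            self.card(country, "HT", "RCP8.5", ht),
        ]

    def test_identical_scorecards_have_zero_flips(self):
        summary = compare_scenarios(self.full_matrix("A", ht="red", lt="red"))
        assert summary.transformation_flips == 0
        assert summary.climate_flips == 0

    def test_transformation_margin_flips_are_counted(self):
        summary = compare_scenarios(self.full_matrix("A"))
        assert summary.transformation_flips == 2  # one per climate level
        assert summary.climate_flips == 0
        assert summary.dominant_factor == "transformation"

    def test_table_has_one_row_per_scenario(self):
        cards = self.full_matrix("A") + self.full_matrix("B")
        assert len(compare_scenarios(cards).table) == 8

    def test_fewer_than_two_scorecards_rejected(self):
        with pytest.raises(ValidationError):
            compare_scenarios(self.full_matrix("A")[:1])
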