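"""Scenario scorecards, calibrated statements and cross-scenario comparison.

Each scenario gets a blue/amber/red verdict per pillar of climate-smart
nutrition security — productivity, adaptation, mitigation and nutrition
security — where blue marks substantial improvement, amber inconclusive
improvement and red clear inadequacy.  A star qualifier marks scenarios
where every aspect of a pillar improves (for nutrition security: every
nutrient requirement met in every trade vignette).  Verdicts are pure
functions of the indicator set and a versioned rule configuration.

Calibrated statements summarize each pillar with a confidence level set
by cross-climate-model agreement in the sign of the pillar indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .climate_smartness import EmissionsLedger, ShockSummary
from .errors import ScoringError, ValidationError

PILLARS = ("productivity", "adaptation", "mitigation", "nutrition_security")
VERDICTS = ("blue", "amber", "red")
VERDICT_RANK = {"red": 0, "amber": 1, "blue": 2}
CONFIDENCE_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class ScoringRules:
    """Scorecard thresholds (see config/scoring_rules.yaml)."""

    rules_version: int = 1
    productivity_blue: float = 0.10
    productivity_red: float = -0.05
    adaptation_blue: float = 0.0
    adaptation_red: float = -0.05
    mitigation_offset_fraction: float = 0.5
    nutrition_target_pct: float = 100.0
    confidence_medium_fraction: float = 0.8

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ScoringRules":
        if path is None:
            text = resources.files("nutriscen.config").joinpath(
                "scoring_rules.yaml"
            ).read_text()
        else:
            text = Path(path).read_text()
        return cls(**yaml.safe_load(text))


@dataclass
class ScenarioIndicators:
    """Everything the scoring rules consume for one scenario."""

    scenario_id: str
    country: str
    transformation: str
    climate_risk: str
    #: Relative change in total (crop + livestock) tonnage vs baseline,
    #: per climate model.
    production_delta_by_model: pd.Series
    #: Tidy adequacy table: columns (vignette, climate_model, nutrient,
    #: ratio_pct, band).
    adequacy: pd.DataFrame
    #: Mid threshold (EAR analogue) as % of the principal target, per
    #: nutrient — the "clearly below requirement" line.
    ear_ratio_pct: pd.Series
    emissions_by_model: dict[str, EmissionsLedger]
    baseline_emissions: EmissionsLedger
    #: Mean principal-requirement ratio at baseline (for improvement
    #: direction) and per (vignette, model) in the future.
    baseline_mean_ratio_pct: float
    shock_summaries: list[ShockSummary] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.production_delta_by_model) == 0:
            raise ScoringError("missing production indicators")
        if self.adequacy.empty:
            raise ScoringError("missing adequacy indicators")
        if not self.emissions_by_model:
            raise ScoringError("missing emissions indicators")


@dataclass(frozen=True)
class Scorecard:
    """Per-scenario pillar verdicts with star qualifiers."""

    scenario_id: str
    country: str
    transformation: str
    climate_risk: str
    verdicts: dict[str, str]
    stars: dict[str, bool]

    def __post_init__(self):
        for pillar in PILLARS:
            if self.verdicts.get(pillar) not in VERDICTS:
                raise ValidationError(f"missing or invalid verdict for {pillar!r}")
            if self.stars.get(pillar) and self.verdicts[pillar] != "blue":
                raise ValidationError("a star requires a blue verdict")

    def as_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "country": self.country,
            "transformation": self.transformation,
            "climate_risk": self.climate_risk,
            "verdicts": dict(self.verdicts),
            "stars": {k: bool(v) for k, v in self.stars.items()},
        }


@dataclass(frozen=True)
class CalibratedStatement:
    """A concise pillar summary tagged with cross-model confidence."""

    pillar: str
    text: str
    confidence: str
    indicators: tuple[str, ...]

    def __post_init__(self):
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(f"invalid confidence {self.confidence!r}")
        if len(self.indicators) < 1:
            raise ValidationError("a statement must cite at least one indicator")


def _median_ratio_table(adequacy: pd.DataFrame) -> pd.DataFrame:
    """Median-across-models principal ratio per (vignette, nutrient)."""
    return (
        adequacy.groupby(["vignette", "nutrient"], sort=False)["ratio_pct"]
        .median()
        .unstack("nutrient")
    )


def score_scenario(indicators: ScenarioIndicators, rules: ScoringRules | None = None) -> Scorecard:
    """Apply the scoring rules to a scenario's indicator set.

    Nutrition security is blue when at least one trade vignette meets
    the principal target for every nutrient (median across climate
    models), red when some nutrient sits below its EAR-analogue line in
    every vignette, amber otherwise; its star requires every nutrient
    requirement met in every vignette.
    """
    rules = rules or ScoringRules.load()
    indicators.validate()
    deltas = indicators.production_delta_by_model.astype(float)

    verdicts: dict[str, str] = {}
    stars: dict[str, bool] = {}

    med = float(deltas.median())
    if med >= rules.productivity_blue:
        verdicts["productivity"] = "blue"
    elif med <= rules.productivity_red:
        verdicts["productivity"] = "red"
    else:
        verdicts["productivity"] = "amber"
    stars["productivity"] = verdicts["productivity"] == "blue" and bool(
        (deltas >= 0).all()
    )

    worst = float(deltas.min())
    if worst >= rules.adaptation_blue:
        verdicts["adaptation"] = "blue"
    elif worst < rules.adaptation_red:
        verdicts["adaptation"] = "red"
    else:
        verdicts["adaptation"] = "amber"
    stars["adaptation"] = verdicts["adaptation"] == "blue" and med >= rules.productivity_blue

    d_net = np.array(
        [l.net - indicators.baseline_emissions.net for l in indicators.emissions_by_model.values()]
    )
    d_gross = np.array(
        [l.gross - indicators.baseline_emissions.gross for l in indicators.emissions_by_model.values()]
    )
    d_soc = np.array(
        [l.soc_delta - indicators.baseline_emissions.soc_delta for l in indicators.emissions_by_model.values()]
    )
    med_net, med_gross, med_soc = map(float, (np.median(d_net), np.median(d_gross), np.median(d_soc)))
    if med_net <= 0:
        verdicts["mitigation"] = "blue"
    elif med_gross > 0 and med_soc >= rules.mitigation_offset_fraction * med_gross:
        verdicts["mitigation"] = "amber"
    else:
        verdicts["mitigation"] = "red"
    stars["mitigation"] = verdicts["mitigation"] == "blue" and med_gross <= 0

    med_ratio = _median_ratio_table(indicators.adequacy)
    ear = indicators.ear_ratio_pct.reindex(med_ratio.columns)
    target = rules.nutrition_target_pct
    vignette_meets_all = (med_ratio >= target).all(axis=1)
    below_ear_everywhere = (med_ratio < ear).all(axis=0)
    if bool(vignette_meets_all.any()):
        verdicts["nutrition_security"] = "blue"
    elif bool(below_ear_everywhere.any()):
        verdicts["nutrition_security"] = "red"
    else:
        verdicts["nutrition_security"] = "amber"
    stars["nutrition_security"] = verdicts["nutrition_security"] == "blue" and bool(
        vignette_meets_all.all()
    )

    return Scorecard(
        scenario_id=indicators.scenario_id,
        country=indicators.country,
        transformation=indicators.transformation,
        climate_risk=indicators.climate_risk,
        verdicts=verdicts,
        stars=stars,
    )


def _confidence(signs: np.ndarray, rules: ScoringRules) -> str:
    n = len(signs)
    if n == 0:
        return "low"
    agree = max((signs >= 0).sum(), (signs < 0).sum()) / n
    if agree == 1.0:
        return "high"
    if agree >= rules.confidence_medium_fraction:
        return "medium"
    return "low"


def generate_statements(
    scorecard: Scorecard,
    indicators: ScenarioIndicators,
    rules: ScoringRules | None = None,
) -> list[CalibratedStatement]:
    """One calibrated statement per pillar.

    Confidence is high when all climate models agree in the sign of the
    pillar indicator, medium when at least the configured fraction
    agree, low otherwise.
    """
    rules = rules or ScoringRules.load()
    deltas = indicators.production_delta_by_model.to_numpy(dtype=float)
    d_net = np.array(
        [l.net - indicators.baseline_emissions.net for l in indicators.emissions_by_model.values()]
    )
    bau = indicators.adequacy[indicators.adequacy["vignette"] == "business_as_usual"]
    if bau.empty:
        bau = indicators.adequacy
    per_model_ratio = bau.groupby("climate_model", sort=False)["ratio_pct"].mean()
    d_nutrition = per_model_ratio.to_numpy() - indicators.baseline_mean_ratio_pct

    med_delta = float(np.median(deltas))
    statements = [
        CalibratedStatement(
            pillar="productivity",
            text=(
                f"Total agricultural production changes by {med_delta:+.0%} vs baseline "
                f"(median across climate models); verdict {scorecard.verdicts['productivity']}."
            ),
            confidence=_confidence(np.sign(deltas), rules),
            indicators=("production_delta_by_model",),
        ),
        CalibratedStatement(
            pillar="adaptation",
            text=(
                f"Worst-case climate-model production change is {float(deltas.min()):+.0%}; "
                f"verdict {scorecard.verdicts['adaptation']}."
            ),
            confidence=_confidence(np.sign(deltas), rules),
            indicators=("production_delta_by_model",),
        ),
        CalibratedStatement(
            pillar="mitigation",
            text=(
                f"Net agricultural emissions change by {float(np.median(d_net)):+,.0f} t CO2e "
                f"(median across models); verdict {scorecard.verdicts['mitigation']}."
            ),
            confidence=_confidence(np.sign(d_net), rules),
            indicators=("emissions_by_model", "baseline_emissions"),
        ),
        CalibratedStatement(
            pillar="nutrition_security",
            text=(
                f"Mean nutrient-requirement ratio moves from "
                f"{indicators.baseline_mean_ratio_pct:.0f}% to "
                f"{float(per_model_ratio.median()):.0f}% under business-as-usual trade; "
                f"verdict {scorecard.verdicts['nutrition_security']}."
            ),
            confidence=_confidence(np.sign(d_nutrition), rules),
            indicators=("adequacy", "baseline_mean_ratio_pct"),
        ),
    ]
    return statements


@dataclass
class ComparisonSummary:
    """Cross-scenario verdict tabulation and margin sensitivity."""

    table: pd.DataFrame
    transformation_flips: int
    climate_flips: int
    flips_by_pillar: pd.DataFrame

    @property
    def dominant_factor(self) -> str:
        if self.transformation_flips > self.climate_flips:
            return "transformation"
        if self.climate_flips > self.transformation_flips:
            return "climate_risk"
        return "tie"


def compare_scenarios(scorecards: list[Scorecard]) -> ComparisonSummary:
    """Tabulate verdicts and count verdict flips along each matrix margin.

    A transformation flip is a (country, climate risk, pillar) where HT
    and LT verdicts differ; a climate flip is a (country, transformation,
    pillar) where the RCP2.6 and RCP8.5 verdicts differ.
    """
    if len(scorecards) < 2:
        raise ValidationError("need at least two scorecards to compare")
    rows = []
    for sc in scorecards:
        row = {
            "scenario_id": sc.scenario_id,
            "country": sc.country,
            "transformation": sc.transformation,
            "climate_risk": sc.climate_risk,
        }
        row.update({p: sc.verdicts[p] for p in PILLARS})
        rows.append(row)
    table = pd.DataFrame(rows)

    t_flips = {p: 0 for p in PILLARS}
    c_flips = {p: 0 for p in PILLARS}
    for p in PILLARS:
        pivot = table.pivot_table(
            index=["country"], columns=["transformation", "climate_risk"],
            values=p, aggfunc="first",
        )
        for country in pivot.index:
            for rcp in ("RCP2.6", "RCP8.5"):
                ht = pivot.at[country, ("HT", rcp)] if ("HT", rcp) in pivot.columns else None
                lt = pivot.at[country, ("LT", rcp)] if ("LT", rcp) in pivot.columns else None
                if ht is not None and lt is not None and ht != lt:
                    t_flips[p] += 1
            for t in ("LT", "HT"):
                lo = pivot.at[country, (t, "RCP2.6")] if (t, "RCP2.6") in pivot.columns else None
                hi = pivot.at[country, (t, "RCP8.5")] if (t, "RCP8.5") in pivot.columns else None
                if lo is not None and hi is not None and lo != hi:
                    c_flips[p] += 1
    flips = pd.DataFrame(
        {"transformation_flips": t_flips, "climate_flips": c_flips}
    )
    return ComparisonSummary(
        table=table,
        transformation_flips=int(flips["transformation_flips"].sum()),
        climate_flips=int(flips["climate_flips"].sum()),
        flips_by_pillar=flips,
    )


def render_markdown(scorecard: Scorecard, statements: list[CalibratedStatement]) -> str:
    """Human-readable per-scenario summary."""
    lines = [
        f"# Scenario {scorecard.scenario_id}",
        "",
        "| Pillar | Verdict | Star |",
        "| --- | --- | --- |",
    ]
    for p in PILLARS:
        star = "*" if scorecard.stars.get(p) else ""
        lines.append(f"| {p} | {scorecard.verdicts[p]} | {star} |")
    lines.append("")
    lines.append("## Calibrated statements")
    for s in statements:
        lines.append(f"- ({s.confidence} confidence) {s.text}")
    return "\n".join(lines) + "\n"
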