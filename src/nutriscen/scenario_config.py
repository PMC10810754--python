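"""Scenario matrix definition, validation and packaged country fixtures.

A country's food-system futures are framed as a 2x2 matrix of critical
uncertainties: the degree of agricultural transformation (LT = low, HT =
high) crossed with the level of climate risk (RCP2.6 = low, RCP8.5 =
high).  Each cell is a :class:`ScenarioSpec` carrying the quantitative
levers agreed for that future: arable/pasture area changes, the yield
trend mode, the adaptation mode, the direction of crop diversification
(expressed as a bound on the national maize area share), irrigation
change, whether land allocation is production-optimized, and the
stakeholder trade-vignette multipliers.

Fixtures for Malawi, South Africa, Tanzania and Zambia are packaged as
YAML files.  Values not stated in the published scenario descriptions
are flagged ``assumed`` inside the fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from .errors import ValidationError

SCHEMA_VERSION = 1

TRANSFORMATIONS = ("LT", "HT")
CLIMATE_RISKS = ("RCP2.6", "RCP8.5")
#: Matrix cells in canonical order: LT before HT, RCP2.6 before RCP8.5.
CELLS = tuple(f"{t}-{r}" for t in TRANSFORMATIONS for r in CLIMATE_RISKS)

YIELD_TREND_MODES = ("full", "half", "none")
ADAPTATION_MODES = ("autonomous", "transformative")
DIVERSIFICATION = ("increase", "decrease", "none")

#: Countries whose LT scenarios carry no yield trend; the intermediate
#: (half) trend is used by South Africa in every cell.
NO_TREND_LT_COUNTRIES = frozenset({"Malawi", "Tanzania", "Zambia"})
HALF_TREND_COUNTRIES = frozenset({"South Africa"})

PACKAGED_COUNTRIES = ("Malawi", "South Africa", "Tanzania", "Zambia")


@dataclass(frozen=True)
class LandZone:
    """A discrete land zone: arable and pasture areas plus expandable land.

    Protected zones contribute no expandable area by definition.
    """

    arable_ha: float
    pasture_ha: float
    expandable_ha: float
    protected: bool = False

    def __post_init__(self):
        for name in ("arable_ha", "pasture_ha", "expandable_ha"):
            if getattr(self, name) < 0:
                raise ValidationError(f"zone {name} must be >= 0")
        if self.protected and self.expandable_ha > 0:
            raise ValidationError("protected zones must have expandable_ha = 0")


@dataclass(frozen=True)
class CountryProfile:
    """Land endowment and analysis windows for one country."""

    name: str
    zones: tuple[LandZone, ...]
    baseline_year_window: tuple[int, int] = (1990, 2010)
    future_year_window: tuple[int, int] = (2040, 2060)

    def __post_init__(self):
        if self.baseline_year_window[1] >= self.future_year_window[0]:
            raise ValidationError("baseline window must precede future window")

    @property
    def arable_ha(self) -> float:
        return sum(z.arable_ha for z in self.zones)

    @property
    def pasture_ha(self) -> float:
        return sum(z.pasture_ha for z in self.zones)

    @property
    def expandable_ha(self) -> float:
        return sum(z.expandable_ha for z in self.zones)

    @property
    def horizon_years(self) -> int:
        """Years between baseline and future window midpoints."""
        b = (self.baseline_year_window[0] + self.baseline_year_window[1]) // 2
        f = (self.future_year_window[0] + self.future_year_window[1]) // 2
        return f - b


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of a country's transformation x climate-risk matrix."""

    country: str
    transformation: str
    climate_risk: str
    arable_area_change: float = 0.0
    pasture_area_change: float = 0.0
    yield_trend_mode: str = "none"
    adaptation_mode: str = "autonomous"
    diversification: str = "none"
    maize_share_bound: float = 1.0
    irrigation_change: float = 0.0
    optimize_allocation: bool = False
    trade_vignette_params: Mapping[str, float] = field(
        default_factory=lambda: {"import_multiplier": 1.0, "export_multiplier": 1.0}
    )

    @property
    def scenario_id(self) -> str:
        return f"{self.country}:{self.transformation}-{self.climate_risk}"

    @property
    def cell(self) -> str:
        return f"{self.transformation}-{self.climate_risk}"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["trade_vignette_params"] = dict(self.trade_vignette_params)
        return d


@dataclass(frozen=True)
class ScenarioSet:
    """All matrix cells across one or more countries."""

    scenarios: tuple[ScenarioSpec, ...]

    def __post_init__(self):
        keys = [(s.country, s.transformation, s.climate_risk) for s in self.scenarios]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (country, transformation, climate_risk) cells")

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    @property
    def countries(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.scenarios:
            seen.setdefault(s.country, None)
        return tuple(seen)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "scenarios": [s.to_dict() for s in self.scenarios],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioSet":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValidationError(f"unsupported schema_version {version!r}")
        return cls(tuple(ScenarioSpec(**s) for s in d["scenarios"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def enumerate_scenarios(
    countries: Iterable[CountryProfile],
    matrix_params: Mapping[str, Mapping[str, Mapping[str, Any]]],
) -> ScenarioSet:
    """Build the full scenario cross for a set of countries.

    ``matrix_params[country][cell]`` holds the quantitative levers for
    each of the four cells (``LT-RCP2.6`` ... ``HT-RCP8.5``).  Ordering
    is deterministic: countries sorted by name, LT before HT, RCP2.6
    before RCP8.5.

    Raises
    ------
    ValidationError
        If any country is missing parameters for a matrix cell.
    """
    specs: list[ScenarioSpec] = []
    for profile in sorted(countries, key=lambda p: p.name):
        cells = matrix_params.get(profile.name)
        if cells is None:
            raise ValidationError(f"no matrix parameters for country {profile.name!r}")
        for cell in CELLS:
            if cell not in cells:
                raise ValidationError(
                    f"missing matrix cell {profile.name!r}:{cell}"
                )
            t, r = cell.split("-", 1)
            params = dict(cells[cell])
            params.pop("assumed", None)  # provenance metadata, not a lever
            spec = ScenarioSpec(
                country=profile.name, transformation=t, climate_risk=r, **params
            )
            violations = validate_spec(spec, profile)
            if violations:
                raise ValidationError(
                    f"invalid cell {spec.scenario_id}: " + "; ".join(violations)
                )
            specs.append(spec)
    return ScenarioSet(tuple(specs))


def validate_spec(spec: ScenarioSpec, profile: CountryProfile) -> list[str]:
    """Return the list of invariant violations for a spec (empty if valid)."""
    v: list[str] = []
    if spec.transformation not in TRANSFORMATIONS:
        v.append(f"transformation must be one of {TRANSFORMATIONS}")
    if spec.climate_risk not in CLIMATE_RISKS:
        v.append(f"climate_risk must be one of {CLIMATE_RISKS}")
    if spec.yield_trend_mode not in YIELD_TREND_MODES:
        v.append(f"yield_trend_mode must be one of {YIELD_TREND_MODES}")
    if spec.adaptation_mode not in ADAPTATION_MODES:
        v.append(f"adaptation_mode must be one of {ADAPTATION_MODES}")
    if spec.diversification not in DIVERSIFICATION:
        v.append(f"diversification must be one of {DIVERSIFICATION}")
    if not 0.0 <= spec.maize_share_bound <= 1.0:
        v.append("maize_share_bound must be in [0, 1]")
    if spec.arable_area_change < -1.0:
        v.append("arable_area_change cannot remove more than all arable land")
    if spec.pasture_area_change < -1.0:
        v.append("pasture_area_change cannot remove more than all pasture")
    for key in ("import_multiplier", "export_multiplier"):
        m = spec.trade_vignette_params.get(key, 1.0)
        if m < 0:
            v.append(f"trade_vignette_params[{key!r}] must be >= 0")

    # Country-specific trend conventions.
    if profile.name in NO_TREND_LT_COUNTRIES and spec.transformation == "LT":
        if spec.yield_trend_mode != "none":
            v.append(f"{profile.name} LT scenarios must use yield_trend_mode='none'")
    if spec.yield_trend_mode == "half" and profile.name not in HALF_TREND_COUNTRIES:
        v.append("half yield trend is reserved for South Africa profiles")
    if profile.name in HALF_TREND_COUNTRIES and spec.yield_trend_mode != "half":
        v.append(f"{profile.name} scenarios must use yield_trend_mode='half'")

    # Expansion must fit inside non-protected expandable land.
    demand = max(spec.arable_area_change, 0.0) * profile.arable_ha
    demand += max(spec.pasture_area_change, 0.0) * profile.pasture_ha
    if demand > profile.expandable_ha * (1 + 1e-9):
        v.append(
            f"requested expansion {demand:.0f} ha exceeds expandable "
            f"land {profile.expandable_ha:.0f} ha"
        )
    return v


def _fixture_path(country_id: str):
    fname = country_id.lower().replace(" ", "_") + ".yaml"
    return resources.files("nutriscen.fixtures").joinpath(fname)


def load_fixture(country_id: str) -> tuple[CountryProfile, dict[str, dict[str, Any]]]:
    """Load a packaged country fixture.

    Returns the country's :class:`CountryProfile` and its per-cell matrix
    parameters, ready for :func:`enumerate_scenarios`.

    Raises
    ------
    KeyError
        If ``country_id`` is not one of the packaged countries.
    """
    if country_id not in PACKAGED_COUNTRIES:
        raise KeyError(
            f"unknown country {country_id!r}; packaged: {PACKAGED_COUNTRIES}"
        )
    raw = yaml.safe_load(_fixture_path(country_id).read_text())
    if raw.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(
            f"fixture {country_id!r} has unsupported schema_version"
        )
    zones = tuple(LandZone(**z) for z in raw["zones"])
    profile = CountryProfile(
        name=raw["country"],
        zones=zones,
        baseline_year_window=tuple(raw["baseline_year_window"]),
        future_year_window=tuple(raw["future_year_window"]),
    )
    return profile, raw["cells"]


def load_all_fixtures() -> tuple[list[CountryProfile], dict[str, dict[str, Any]]]:
    """Load every packaged country fixture."""
    profiles = []
    matrix: dict[str, dict[str, Any]] = {}
    for c in PACKAGED_COUNTRIES:
        profile, cells = load_fixture(c)
        profiles.append(profile)
        matrix[profile.name] = cells
    return profiles, matrix
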