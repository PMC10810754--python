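"""Surrogate climate-smartness accounting: emissions, soil organic
carbon and extreme-yield shocks.

Gross agricultural emissions are emission-factor products over crop
production, livestock output and land-use change from agricultural
expansion.  Soil organic carbon (SOC) change is a declared surrogate —
a linear response to the organic-input proxy (crop production times a
residue-return fraction) — standing in for process-based SOC
modelling; increased organic inputs sequester carbon and partially
offset gross emissions.

A yield shock is a year whose yield falls below half the baseline mean
("approximately half" is operationalized as strictly below 0.5x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError


@dataclass(frozen=True)
class SocParams:
    """Linear SOC surrogate: soc_delta = rate x organic-input proxy."""

    sequestration_rate: float = 0.05  # t CO2e per t organic input
    residue_return_fraction: float = 0.3


@dataclass
class EmissionsLedger:
    """Per-scenario emissions account (t CO2e).

    ``net = crop + livestock + luc - soc_delta`` holds exactly;
    positive ``soc_delta`` is sequestration.
    """

    crop_emissions: float
    livestock_emissions: float
    luc_emissions: float
    soc_delta: float

    def __post_init__(self):
        if min(self.crop_emissions, self.livestock_emissions, self.luc_emissions) < 0:
            raise ValidationError("gross emission components must be >= 0")

    @property
    def gross(self) -> float:
        return self.crop_emissions + self.livestock_emissions + self.luc_emissions

    @property
    def net(self) -> float:
        return self.gross - self.soc_delta

    def as_dict(self) -> dict[str, float]:
        return {
            "crop_emissions_tco2e": self.crop_emissions,
            "livestock_emissions_tco2e": self.livestock_emissions,
            "luc_emissions_tco2e": self.luc_emissions,
            "soc_delta_tco2e": self.soc_delta,
            "gross_tco2e": self.gross,
            "net_tco2e": self.net,
        }


@dataclass
class ShockSummary:
    """Extreme-yield shock statistics for one crop."""

    crop: str
    n_years: int
    shock_count: int
    threshold_t_ha: float

    @property
    def frequency_per_decade(self) -> float:
        return 10.0 * self.shock_count / self.n_years


#: Packaged default emission factors (t CO2e per t product; LUC per ha
#: expanded).  Provenance: assumed surrogate values, user-overridable.
DEFAULT_EMISSION_FACTORS = {
    "crop_default": 0.35,
    "luc_per_ha": 100.0,
    "livestock": {
        "bovine_meat": 30.0,
        "bovine_milk": 3.0,
        "sheep_goat_meat": 20.0,
        "sheep_goat_milk": 3.5,
        "pig_meat": 6.0,
        "poultry_meat": 4.0,
        "eggs": 3.5,
    },
}


@dataclass
class EmissionFactors:
    """Emission-factor table; any commodity/category can be overridden."""

    crop: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    livestock: pd.Series = field(
        default_factory=lambda: pd.Series(DEFAULT_EMISSION_FACTORS["livestock"])
    )
    crop_default: float = DEFAULT_EMISSION_FACTORS["crop_default"]
    luc_per_ha: float = DEFAULT_EMISSION_FACTORS["luc_per_ha"]

    def crop_factor(self, commodities) -> pd.Series:
        return self.crop.reindex(commodities).fillna(self.crop_default)


def compute_emissions(
    crop_production: pd.Series,
    livestock_output: pd.Series,
    expanded_area_ha: float,
    factors: EmissionFactors | None = None,
    soc_params: SocParams = SocParams(),
) -> EmissionsLedger:
    """Build the emissions ledger for one scenario realization.

    Raises
    ------
    CoverageError
        If a livestock category lacks an emission factor.
    """
    factors = factors or EmissionFactors()
    crop_prod = crop_production.astype(float)
    if (crop_prod < 0).any() or (livestock_output < 0).any():
        raise ValidationError("production must be >= 0")
    ef_l = factors.livestock.reindex(livestock_output.index)
    if ef_l.isna().any():
        raise CoverageError(
            f"missing livestock emission factors: {list(ef_l.index[ef_l.isna()])}"
        )
    crop_em = float((crop_prod * factors.crop_factor(crop_prod.index)).sum())
    livestock_em = float((livestock_output * ef_l).sum())
    luc_em = max(expanded_area_ha, 0.0) * factors.luc_per_ha
    organic_input = float(crop_prod.sum()) * soc_params.residue_return_fraction
    soc_delta = soc_params.sequestration_rate * organic_input
    return EmissionsLedger(
        crop_emissions=crop_em,
        livestock_emissions=livestock_em,
        luc_emissions=luc_em,
        soc_delta=soc_delta,
    )


def count_yield_shocks(
    series: pd.Series | np.ndarray,
    baseline_mean: float,
    crop: str = "",
) -> ShockSummary:
    """Count years with yield strictly below half the baseline mean."""
    values = np.asarray(series, dtype=float)
    if values.size < 1:
        raise ValidationError("series must have at least one year")
    if baseline_mean <= 0:
        raise ValidationError("baseline_mean must be > 0")
    threshold = 0.5 * baseline_mean
    count = int((values < threshold).sum())
    return ShockSummary(
        crop=crop, n_years=values.size, shock_count=count, threshold_t_ha=threshold
    )
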