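"""Mid-century crop production projection.

Per-commodity, per-zone yields are projected as

    projected = (baseline + trend) * (1 + adaptation uplift)
                * irrigation multiplier * climate factor

where the trend term extrapolates the historical linear yield trend
(full, half or none), the adaptation uplift depends on whether
adaptation is autonomous (planting dates and existing varieties, which
leaves a residual growing-season-loss penalty) or transformative (new
varieties that cancel that penalty), and the climate factor is an
exogenous per-climate-model multiplier.

National production is then either evaluated at baseline crop-area
shares (low-transformation scenarios) or obtained from a linear program
that distributes zone areas across crops to maximize total production
subject to national crop-share bounds (the diversification levers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import AllocationInfeasibleError, ValidationError
from .scenario_config import CountryProfile, ScenarioSpec


@dataclass(frozen=True)
class AdaptationParams:
    """Yield response to the two adaptation modes.

    ``growing_season_penalty`` is the residual yield loss from a
    warming-shortened growing season that only transformative
    adaptation (new varieties) cancels.
    """

    autonomous_uplift: float = 0.05
    transformative_uplift: float = 0.10
    growing_season_penalty: float = 0.05

    def __post_init__(self):
        if self.autonomous_uplift < -1 or self.transformative_uplift < -1:
            raise ValidationError("adaptation uplift must be > -1")
        if self.autonomous_uplift > self.transformative_uplift:
            raise ValidationError(
                "autonomous uplift cannot exceed transformative uplift"
            )
        if not 0 <= self.growing_season_penalty < 1:
            raise ValidationError("growing_season_penalty must be in [0, 1)")


@dataclass(frozen=True)
class IrrigationParams:
    """Irrigation lever: a yield boost on the irrigable area fraction."""

    irrigable_fraction: float = 0.2
    yield_boost: float = 0.5


@dataclass
class AllocationPlan:
    """Result of the production-maximizing land allocation."""

    area: pd.DataFrame  # zones x commodities, ha
    objective: float  # national production, t
    binding_constraints: list[str] = field(default_factory=list)


def apply_yield_trend(
    baseline_yield: float | np.ndarray,
    slope: float | np.ndarray,
    mode: str,
    horizon_years: int,
) -> float | np.ndarray:
    """Extrapolate the historical linear yield trend to the horizon.

    ``full`` continues the historical trend, ``half`` applies half of
    it, ``none`` holds yields at baseline.  Results are floored at 0.
    """
    if horizon_years < 0:
        raise ValidationError("horizon_years must be >= 0")
    if np.any(np.asarray(baseline_yield) < 0):
        raise ValidationError("baseline yield must be >= 0")
    factor = {"full": 1.0, "half": 0.5, "none": 0.0}.get(mode)
    if factor is None:
        raise ValidationError(f"unknown yield trend mode {mode!r}")
    out = np.maximum(baseline_yield + factor * slope * horizon_years, 0.0)
    return float(out) if np.isscalar(baseline_yield) else out


def apply_adaptation(
    yield_t_ha: float | np.ndarray,
    mode: str,
    params: AdaptationParams = AdaptationParams(),
) -> float | np.ndarray:
    """Apply the adaptation-mode multiplier to a yield."""
    if mode == "autonomous":
        mult = (1 + params.autonomous_uplift) * (1 - params.growing_season_penalty)
    elif mode == "transformative":
        mult = 1 + params.transformative_uplift
    else:
        raise ValidationError(f"unknown adaptation mode {mode!r}")
    out = np.asarray(yield_t_ha) * mult
    return float(out) if np.isscalar(yield_t_ha) else out


def fit_trend_slopes(yield_history: pd.DataFrame) -> pd.Series:
    """Per-commodity linear yield-trend slopes (t/ha/yr) by OLS.

    ``yield_history`` is indexed by year with one column per commodity.
    """
    years = yield_history.index.to_numpy(dtype=float)
    slopes = {
        c: float(np.polyfit(years, yield_history[c].to_numpy(dtype=float), 1)[0])
        for c in yield_history.columns
    }
    return pd.Series(slopes, name="slope_t_ha_yr")


def allocate_crops(
    yields: pd.DataFrame,
    zone_areas: pd.Series,
    share_bounds: Mapping[str, tuple[float, float]] | None = None,
    *,
    rtol: float = 1e-9,
) -> AllocationPlan:
    """Distribute zone areas across crops to maximize national production.

    Solves the LP

        max  sum_{z,c} x_{zc} * y_{zc}
        s.t. sum_c x_{zc} <= area_z            (zone land)
             l_c * A <= sum_z x_{zc} <= u_c * A (national share bounds)
             x >= 0

    with ``A`` the total zone area.  ``share_bounds`` maps a commodity
    to its (min, max) national area share; unbounded commodities get
    (0, 1).  Ties are broken deterministically by a vanishing
    lexicographic preference over (commodity, zone) order.

    Raises
    ------
    AllocationInfeasibleError
        If the share bounds are mutually infeasible.
    """
    zones = list(yields.index)
    crops = list(yields.columns)
    if list(zone_areas.index) != zones:
        zone_areas = zone_areas.reindex(zones)
    if zone_areas.isna().any() or (zone_areas < 0).any():
        raise ValidationError("zone areas must be >= 0 and cover all zones")
    y = yields.to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValidationError("yields must be >= 0")
    a = zone_areas.to_numpy(dtype=float)
    total = float(a.sum())
    nz, nc = y.shape

    bounds = {c: (0.0, 1.0) for c in crops}
    if share_bounds:
        for c, (lo, hi) in share_bounds.items():
            if c in bounds:
                bounds[c] = (float(lo), float(hi))
    lo_sum = sum(b[0] for b in bounds.values())
    conflicts = [
        f"min share sum {lo_sum:.3f} > 1" if lo_sum > 1 + 1e-12 else "",
        *(
            f"{c}: min {lo} > max {hi}"
            for c, (lo, hi) in bounds.items()
            if lo > hi
        ),
    ]
    conflicts = [c for c in conflicts if c]
    if conflicts:
        raise AllocationInfeasibleError(
            "infeasible share bounds: " + "; ".join(conflicts), conflicts
        )

    # Variables x[z, c] flattened row-major.  Objective: maximize, so
    # negate; a vanishing perturbation favoring low (commodity, zone)
    # indices makes the tie-break deterministic.
    rank = np.arange(nc)[None, :] * nz + np.arange(nz)[:, None]
    lex = (nz * nc - rank) / (nz * nc)
    scale = max(y.max(), 1.0)
    c_vec = -(y + 1e-9 * scale * lex).ravel()

    A_ub, b_ub = [], []
    for z in range(nz):  # zone land constraints
        row = np.zeros(nz * nc)
        row[z * nc : (z + 1) * nc] = 1.0
        A_ub.append(row)
        b_ub.append(a[z])
    for j, c in enumerate(crops):  # national share bounds
        lo, hi = bounds[c]
        col = np.zeros(nz * nc)
        col[j::nc] = 1.0
        if hi < 1.0:
            A_ub.append(col)
            b_ub.append(hi * total)
        if lo > 0.0:
            A_ub.append(-col)
            b_ub.append(-lo * total)

    res = linprog(
        c_vec,
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        bounds=(0, None),
        method="highs",
    )
    if res.status == 2:
        raise AllocationInfeasibleError(
            "allocation LP infeasible under the given share bounds",
            [f"{c}: share in {bounds[c]}" for c in crops],
        )
    if not res.success:  # pragma: no cover - solver failure
        raise AllocationInfeasibleError(f"LP solver failed: {res.message}")

    x = res.x.reshape(nz, nc)
    x[x < 1e-9 * max(total, 1.0)] = 0.0
    area = pd.DataFrame(x, index=zones, columns=crops)
    objective = float((x * y).sum())

    binding = []
    used = x.sum(axis=1)
    for z, zone in enumerate(zones):
        if a[z] > 0 and used[z] >= a[z] * (1 - 1e-9):
            binding.append(f"zone:{zone}")
    nat = x.sum(axis=0)
    for j, c in enumerate(crops):
        lo, hi = bounds[c]
        if hi < 1.0 and nat[j] >= hi * total * (1 - 1e-9):
            binding.append(f"max_share:{c}")
        if lo > 0.0 and nat[j] <= lo * total * (1 + 1e-9):
            binding.append(f"min_share:{c}")
    return AllocationPlan(area=area, objective=objective, binding_constraints=binding)


def diversification_bounds(
    spec: ScenarioSpec,
    commodities: list[str],
    baseline_shares: pd.Series,
    maize: str = "maize",
) -> dict[str, tuple[float, float]]:
    """Translate the diversification lever into national share bounds.

    Increased diversification caps maize (and every other crop) at the
    spec's share bound while flooring each crop at half its baseline
    share, so the optimizer spreads area across more crops.  Decreased
    diversification floors maize at the bound (a re-concentration on
    the staple).  With no diversification signal the optimizer is only
    tied to baseline diversity through mild floors.
    """
    shares = baseline_shares.reindex(commodities).fillna(0.0)
    if spec.diversification == "increase":
        cap = spec.maize_share_bound
        return {
            c: (min(0.5 * shares[c], cap * 0.999), cap) for c in commodities
        }
    if spec.diversification == "decrease":
        out = {c: (0.0, 1.0) for c in commodities}
        out[maize] = (spec.maize_share_bound, 1.0) if maize in commodities else (0.0, 1.0)
        return out
    return {c: (0.25 * shares[c], 1.0) for c in commodities}


def expand_zone_areas(
    profile: CountryProfile, arable_area_change: float
) -> pd.Series:
    """Future arable area per zone under the scenario's area change.

    Expansion is drawn from each zone's expandable land in proportion
    to its share of national expandable land, so protected zones never
    expand.  Contraction scales every zone's arable area uniformly.
    """
    base = np.array([z.arable_ha for z in profile.zones], dtype=float)
    if arable_area_change >= 0:
        demand = arable_area_change * base.sum()
        expandable = np.array([z.expandable_ha for z in profile.zones], dtype=float)
        if demand > expandable.sum() * (1 + 1e-9):
            raise ValidationError(
                f"arable expansion {demand:.0f} ha exceeds expandable land "
                f"{expandable.sum():.0f} ha"
            )
        add = expandable * (demand / expandable.sum()) if expandable.sum() > 0 else 0.0
        future = base + add
    else:
        future = base * (1 + arable_area_change)
    return pd.Series(future, index=range(len(profile.zones)), name="area_ha")


def project_yields(
    spec: ScenarioSpec,
    baseline_yields: pd.DataFrame,
    slopes: pd.Series,
    horizon_years: int,
    climate_factors: pd.DataFrame | None = None,
    adaptation: AdaptationParams = AdaptationParams(),
    irrigation: IrrigationParams = IrrigationParams(),
) -> dict[str, pd.DataFrame]:
    """Projected zone x commodity yields for each climate model.

    ``baseline_yields`` is zones x commodities (t/ha); ``climate_factors``
    has a (climate_model, zone) MultiIndex with one column per commodity
    (``None`` means unit factors for a single nominal model).
    """
    trended = apply_yield_trend(
        baseline_yields.to_numpy(),
        slopes.reindex(baseline_yields.columns).fillna(0.0).to_numpy()[None, :],
        spec.yield_trend_mode,
        horizon_years,
    )
    adapted = apply_adaptation(trended, spec.adaptation_mode, adaptation)
    irr_mult = 1.0 + spec.irrigation_change * irrigation.irrigable_fraction * irrigation.yield_boost
    adapted = adapted * irr_mult

    out: dict[str, pd.DataFrame] = {}
    if climate_factors is None:
        out["nominal"] = pd.DataFrame(
            adapted, index=baseline_yields.index, columns=baseline_yields.columns
        )
        return out
    for model in climate_factors.index.get_level_values(0).unique():
        f = (
            climate_factors.loc[model]
            .reindex(index=baseline_yields.index, columns=baseline_yields.columns)
            .to_numpy()
        )
        out[str(model)] = pd.DataFrame(
            np.maximum(adapted * f, 0.0),
            index=baseline_yields.index,
            columns=baseline_yields.columns,
        )
    return out


def project_production(
    spec: ScenarioSpec,
    profile: CountryProfile,
    baseline_areas: pd.DataFrame,
    baseline_yields: pd.DataFrame,
    slopes: pd.Series,
    climate_factors: pd.DataFrame | None = None,
    adaptation: AdaptationParams = AdaptationParams(),
    irrigation: IrrigationParams = IrrigationParams(),
) -> pd.DataFrame:
    """Project per-commodity production for each climate model.

    Low-transformation scenarios retain baseline crop-area shares
    (rescaled to the future zone areas); optimizing scenarios solve the
    allocation LP per climate model under the diversification bounds.

    Returns a tidy frame with columns (climate_model, commodity, zone,
    area_ha, yield_t_ha, production_t).
    """
    zones = list(baseline_areas.index)
    crops = list(baseline_areas.columns)
    future_zone_area = expand_zone_areas(profile, spec.arable_area_change)
    future_zone_area.index = zones

    yields_by_model = project_yields(
        spec, baseline_yields, slopes, profile.horizon_years,
        climate_factors, adaptation, irrigation,
    )

    base_total = baseline_areas.to_numpy().sum()
    national_shares = baseline_areas.sum(axis=0) / base_total if base_total > 0 else None

    records = []
    for model, ymat in yields_by_model.items():
        if spec.optimize_allocation:
            bounds = diversification_bounds(spec, crops, national_shares)
            plan = allocate_crops(ymat, future_zone_area, bounds)
            area = plan.area
        else:
            # Baseline within-zone crop mix, rescaled to future zone areas.
            zone_tot = baseline_areas.sum(axis=1)
            mix = baseline_areas.div(zone_tot.replace(0.0, np.nan), axis=0).fillna(0.0)
            area = mix.mul(future_zone_area, axis=0)
        prod = area * ymat
        for z in zones:
            for c in crops:
                records.append(
                    (model, c, z, area.at[z, c], ymat.at[z, c], prod.at[z, c])
                )
    return pd.DataFrame(
        records,
        columns=[
            "climate_model", "commodity", "zone",
            "area_ha", "yield_t_ha", "production_t",
        ],
    )


def national_production(production: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a tidy production table to (climate_model x commodity) totals."""
    return (
        production.groupby(["climate_model", "commodity"], sort=False)["production_t"]
        .sum()
        .unstack("commodity")
    )
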