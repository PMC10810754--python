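"""Livestock output projection from feed availability.

Seven output categories are tracked: bovine meat, bovine milk, sheep
and goat meat, sheep and goat milk, pig meat, poultry meat and eggs.
Feed reaches livestock through three streams — pasture, crop residues
and feed crops — split among categories by fixed allocation shares.
Baseline feed-to-output ratios are fitted once and held constant to
mid-century, so projected output responds linearly to the future feed
basket (pasture scales with the scenario's pasture-area change; residue
and feed-crop streams scale with projected crop production).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .scenario_config import ScenarioSpec

LIVESTOCK_CATEGORIES = (
    "bovine_meat",
    "bovine_milk",
    "sheep_goat_meat",
    "sheep_goat_milk",
    "pig_meat",
    "poultry_meat",
    "eggs",
)

FEED_STREAMS = ("pasture", "residues", "feedcrops")


@dataclass
class FeedBasket:
    """Feed supply by stream (t dry matter) and category allocation shares.

    ``allocation_shares`` is a categories x streams frame; each stream
    column sums to at most 1 (the remainder is unallocated feed).
    """

    pasture_t: float
    residues_t: float
    feedcrops_t: float
    allocation_shares: pd.DataFrame

    def __post_init__(self):
        if min(self.pasture_t, self.residues_t, self.feedcrops_t) < 0:
            raise ValidationError("feed supplies must be >= 0")
        s = self.allocation_shares
        missing = set(FEED_STREAMS) - set(s.columns)
        if missing:
            raise ValidationError(f"allocation_shares missing streams {sorted(missing)}")
        if (s.to_numpy() < 0).any():
            raise ValidationError("allocation shares must be >= 0")
        if (s.sum(axis=0) > 1 + 1e-9).any():
            raise ValidationError("allocation shares per stream must sum to <= 1")

    @property
    def supply(self) -> pd.Series:
        return pd.Series(
            [self.pasture_t, self.residues_t, self.feedcrops_t], index=FEED_STREAMS
        )

    def allocated_feed(self) -> pd.Series:
        """Total feed (t) reaching each category across streams."""
        return (self.allocation_shares * self.supply).sum(axis=1)

    def scaled(self, factors: pd.Series | dict) -> "FeedBasket":
        f = pd.Series(factors).reindex(FEED_STREAMS).fillna(1.0)
        return FeedBasket(
            pasture_t=self.pasture_t * f["pasture"],
            residues_t=self.residues_t * f["residues"],
            feedcrops_t=self.feedcrops_t * f["feedcrops"],
            allocation_shares=self.allocation_shares,
        )


def fit_feed_ratios(basket: FeedBasket, baseline_output: pd.Series) -> pd.Series:
    """Baseline output per tonne of allocated feed, per category.

    Categories with zero output get ratio 0.  A category with output
    but no allocated feed is unexplainable under the feed model.
    """
    out = baseline_output.reindex(LIVESTOCK_CATEGORIES).fillna(0.0)
    feed = basket.allocated_feed().reindex(LIVESTOCK_CATEGORIES).fillna(0.0)
    bad = out[(out > 0) & (feed <= 0)]
    if len(bad):
        raise DataError(
            f"nonzero output with zero allocated feed for: {list(bad.index)}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(out > 0, out / feed.replace(0.0, np.nan), 0.0)
    return pd.Series(np.nan_to_num(ratios), index=LIVESTOCK_CATEGORIES, name="ratio")


def project_livestock(
    spec: ScenarioSpec,
    future_basket: FeedBasket,
    ratios: pd.Series,
) -> pd.Series:
    """Projected output (t) per category: ratio x future allocated feed.

    The pasture stream of ``future_basket`` is additionally scaled by
    the scenario's pasture-area change (pasture supply tracks pasture
    area one-for-one).
    """
    if spec.pasture_area_change < -1:
        raise ValidationError("pasture_area_change cannot remove more than all pasture")
    basket = future_basket.scaled({"pasture": 1 + spec.pasture_area_change})
    feed = basket.allocated_feed().reindex(LIVESTOCK_CATEGORIES).fillna(0.0)
    if (feed < 0).any():
        raise ValidationError("allocated feed must be >= 0")
    out = ratios.reindex(LIVESTOCK_CATEGORIES).fillna(0.0) * feed
    out.name = "production_t"
    return out


def residue_supply(
    crop_production: pd.Series, residue_fractions: pd.Series | dict
) -> float:
    """Crop-residue feed stream: per-commodity residue fractions x production."""
    frac = pd.Series(residue_fractions).reindex(crop_production.index).fillna(0.0)
    return float((crop_production * frac).sum())
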