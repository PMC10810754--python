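"""Per-commodity food balances and trade vignettes.

A food balance allocates each commodity's total supply across uses via
the identity

    food = production + imports - exports - stock_change
           - feed - seed - losses

The three trade vignettes close the balance differently:

* ``self_sufficiency`` — no imports or exports; how well domestic
  production alone matches domestic requirements.
* ``business_as_usual`` — imports and exports keep their baseline
  proportions to domestic production.
* ``stakeholder`` — baseline-proportional flows rescaled by per-scenario
  expert import/export multipliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AccountingError, ValidationError

logger = logging.getLogger(__name__)

VIGNETTES = ("self_sufficiency", "business_as_usual", "stakeholder")

FLOW_COLUMNS = (
    "production", "imports", "exports", "stock_change",
    "feed", "seed", "losses", "food",
)


@dataclass(frozen=True)
class TradeVignette:
    """A trade closure rule; multipliers only apply to the stakeholder kind."""

    kind: str
    import_multiplier: float = 1.0
    export_multiplier: float = 1.0

    def __post_init__(self):
        if self.kind not in VIGNETTES:
            raise ValidationError(f"unknown vignette kind {self.kind!r}")
        if self.import_multiplier < 0 or self.export_multiplier < 0:
            raise ValidationError("vignette multipliers must be >= 0")


@dataclass
class TradeRatios:
    """Baseline import/export-to-production ratios with absolute fallbacks.

    When a commodity had no baseline production but nonzero trade, the
    proportional rule is undefined; the absolute baseline flows are held
    instead (and the fallback is logged when used).
    """

    import_ratio: pd.Series
    export_ratio: pd.Series
    fallback_imports: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    fallback_exports: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def fit_trade_ratios(
    baseline_production: pd.Series,
    baseline_imports: pd.Series,
    baseline_exports: pd.Series,
) -> TradeRatios:
    """Per-commodity baseline trade-to-production ratios."""
    prod = baseline_production.astype(float)
    imp = baseline_imports.reindex(prod.index).fillna(0.0)
    exp = baseline_exports.reindex(prod.index).fillna(0.0)
    zero = prod <= 0
    safe = prod.where(~zero, np.nan)
    return TradeRatios(
        import_ratio=(imp / safe).fillna(0.0),
        export_ratio=(exp / safe).fillna(0.0),
        fallback_imports=imp.where(zero, 0.0),
        fallback_exports=exp.where(zero, 0.0),
    )


def build_balance(
    production: pd.Series,
    use_shares: pd.DataFrame,
    imports: pd.Series | None = None,
    exports: pd.Series | None = None,
    stock_change: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble a per-commodity food balance.

    ``use_shares`` has columns ``feed``, ``seed``, ``losses`` giving the
    fraction of production flowing to each non-food use (the future
    evolution of non-food uses mirrors production, the same
    proportionality principle as business-as-usual trade).

    Raises
    ------
    AccountingError
        If any commodity's computed food supply is negative.
    """
    idx = production.index
    prod = production.astype(float)
    if (prod < 0).any():
        raise ValidationError("production must be >= 0")
    shares = use_shares.reindex(idx).fillna(0.0)
    for col in ("feed", "seed", "losses"):
        if col not in shares.columns:
            raise ValidationError(f"use_shares missing column {col!r}")
    if (shares[["feed", "seed", "losses"]].sum(axis=1) > 1 + 1e-9).any():
        raise ValidationError("use shares must sum to <= 1 per commodity")

    def _flow(s, name):
        if s is None:
            return pd.Series(0.0, index=idx)
        s = s.reindex(idx).fillna(0.0).astype(float)
        if name != "stock_change" and (s < 0).any():
            raise ValidationError(f"{name} must be >= 0")
        return s

    imp = _flow(imports, "imports")
    exp = _flow(exports, "exports")
    stock = _flow(stock_change, "stock_change")
    feed = shares["feed"] * prod
    seed = shares["seed"] * prod
    losses = shares["losses"] * prod
    food = prod + imp - exp - stock - feed - seed - losses
    neg = food[food < -1e-6]
    if len(neg):
        raise AccountingError(
            f"negative food supply for commodities: {list(neg.index)}"
        )
    balance = pd.DataFrame(
        {
            "production": prod, "imports": imp, "exports": exp,
            "stock_change": stock, "feed": feed, "seed": seed,
            "losses": losses, "food": food.clip(lower=0.0),
        },
        index=idx,
    )
    assert_identity(balance)
    return balance


def assert_identity(balance: pd.DataFrame, atol: float = 1e-6) -> None:
    """Assert the food-balance identity holds for every commodity."""
    lhs = balance["food"]
    rhs = (
        balance["production"] + balance["imports"] - balance["exports"]
        - balance["stock_change"] - balance["feed"] - balance["seed"]
        - balance["losses"]
    )
    resid = (lhs - rhs).abs()
    scale = balance["production"].abs().clip(lower=1.0)
    if (resid > atol * scale + atol).any():
        bad = resid[resid > atol * scale + atol]
        raise AccountingError(f"balance identity violated for {list(bad.index)}")


def apply_trade_vignette(
    balance: pd.DataFrame,
    vignette: TradeVignette,
    ratios: TradeRatios | None = None,
) -> pd.DataFrame:
    """Re-close a balance under a trade vignette.

    Non-trade flows are kept; imports/exports are replaced by the
    vignette rule and food recomputed.  If a stakeholder export
    multiplier would push food below zero, exports are capped at
    availability (logged) — the balance never reports negative food.
    """
    out = balance.copy()
    prod = out["production"]
    if vignette.kind == "self_sufficiency":
        imp = pd.Series(0.0, index=out.index)
        exp = pd.Series(0.0, index=out.index)
    else:
        if ratios is None:
            raise ValidationError(f"{vignette.kind} vignette requires baseline ratios")
        imp = ratios.import_ratio.reindex(out.index).fillna(0.0) * prod
        exp = ratios.export_ratio.reindex(out.index).fillna(0.0) * prod
        fb_imp = ratios.fallback_imports.reindex(out.index).fillna(0.0)
        fb_exp = ratios.fallback_exports.reindex(out.index).fillna(0.0)
        used_fallback = (fb_imp > 0) | (fb_exp > 0)
        if used_fallback.any():
            logger.warning(
                "proportional trade undefined (zero baseline production); "
                "holding absolute baseline flows for %s",
                list(out.index[used_fallback]),
            )
            imp = imp.where(~used_fallback, fb_imp)
            exp = exp.where(~used_fallback, fb_exp)
        if vignette.kind == "stakeholder":
            imp = imp * vignette.import_multiplier
            exp = exp * vignette.export_multiplier
    food = (
        prod + imp - exp - out["stock_change"]
        - out["feed"] - out["seed"] - out["losses"]
    )
    short = food < 0
    if short.any():
        logger.warning(
            "vignette %s exports capped at availability for %s",
            vignette.kind, list(out.index[short]),
        )
        exp = exp.where(~short, exp + food)  # reduce exports by the shortfall
        exp = exp.clip(lower=0.0)
        food = (
            prod + imp - exp - out["stock_change"]
            - out["feed"] - out["seed"] - out["losses"]
        )
    neg = food[food < -1e-6]
    if len(neg):
        raise AccountingError(f"negative food after vignette for {list(neg.index)}")
    out["imports"] = imp
    out["exports"] = exp
    out["food"] = food.clip(lower=0.0)
    assert_identity(out)
    return out


def net_trade_position(balance: pd.DataFrame) -> float:
    """Signed net tonnage: total imports minus total exports (positive = net importer)."""
    return float(balance["imports"].sum() - balance["exports"].sum())


def vignette_from_spec(kind: str, params: Mapping[str, float]) -> TradeVignette:
    """Build a vignette, reading stakeholder multipliers from scenario params."""
    if kind == "stakeholder":
        return TradeVignette(
            kind=kind,
            import_multiplier=float(params.get("import_multiplier", 1.0)),
            export_multiplier=float(params.get("export_multiplier", 1.0)),
        )
    return TradeVignette(kind=kind)
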