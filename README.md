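# nutriscen

Integrated scenario assessment of **climate-smart agriculture and
population-level nutrition security** for food-system planners and
researchers. The package asks: under a stakeholder-style 2×2 matrix of
futures — agricultural **transformation** (LT/HT) crossed with
**climate risk** (RCP2.6/RCP8.5) — will a country's mid-century food
supply meet its population's energy and nutrient requirements, and at
what cost in greenhouse-gas emissions?

It is aimed at integrated-assessment and nutrition-surveillance work
where the full chain — production projection, trade, food-balance
accounting, nutrient adequacy, emissions — must run reproducibly at
desk scale. A synthetic-data generator supplies all baseline inputs
(no downloads), with *designed* adequacy gaps so that downstream
verdicts are known by construction and the pipeline is testable.

## The model

**Crop projection.** For commodity *c* in zone *z* under climate model
*m*, the mid-century yield is

    y_zcm = (y_zc + β_c·h) · (1 + a) · g · f_zcm

where `β_c` is the historical linear yield trend (OLS on a 1960–2010
series; applied in full, half or not at all per scenario), `h` the
horizon in years, `a` the adaptation uplift (autonomous adaptation
keeps a residual growing-season-loss penalty; transformative
adaptation cancels it), `g` an irrigation multiplier and `f_zcm` an
exogenous per-climate-model impact factor. National production either
keeps baseline area shares (LT) or solves the LP

    max Σ_zc x_zc · y_zc   s.t.  Σ_c x_zc ≤ A_z,
                                 l_c·A ≤ Σ_z x_zc ≤ u_c·A,  x ≥ 0

with maize share bounds encoding the diversification lever. Livestock
output for the seven categories (bovine meat/milk, sheep & goat
meat/milk, pig meat, poultry meat, eggs) is projected linearly from the
feed basket (pasture, crop residues, feed crops) using baseline
feed-to-output ratios held constant.

**Food balances and trade.** Per commodity,

    food = production + imports − exports − Δstock − feed − seed − losses

closed under three trade vignettes: *self-sufficiency* (no trade),
*business-as-usual* (trade keeps baseline proportions to production)
and *stakeholder* (expert import/export multipliers).

**Nutrient adequacy.** The food column is disaggregated into weighted
food items, discounted for inedible fractions and household waste,
converted through food-composition densities and divided by the
projected population. Supply is classified against three ascending
population-weighted thresholds per nutrient — LRNI / EAR / RNI for
micronutrients and protein (RNI is the principal target), minimum /
midpoint / maximum intakes for fat, minimum / average / maximum
dietary energy requirements for energy (supply at or above the maximum
is an oversupply flag).

**Climate smartness.** Emission-factor accounting over production plus
land-use-change emissions from expansion, partially offset by a soil-
organic-carbon surrogate that grows with organic inputs; extreme-yield
shocks are years below half the baseline mean yield.

**Scorecards.** Each scenario gets blue / amber / red verdicts for
productivity, adaptation, mitigation and nutrition security (blue =
substantial improvement, amber = inconclusive, red = clear
inadequacy), star qualifiers when every aspect of a pillar improves,
and calibrated statements whose confidence reflects cross-climate-model
agreement.

## Worked example

```python
import nutriscen as ns

run = ns.run_country("Zambia", seed=1)
for cell, result in run.results.items():
    print(cell, result.scorecard.verdicts)
print(run.baseline_adequacy[["ratio_pct", "band"]])
```

prints

```
LT-RCP2.6 {'productivity': 'amber', 'adaptation': 'amber', 'mitigation': 'blue', 'nutrition_security': 'red'}
LT-RCP8.5 {'productivity': 'amber', 'adaptation': 'red', 'mitigation': 'blue', 'nutrition_security': 'red'}
HT-RCP2.6 {'productivity': 'blue', 'adaptation': 'blue', 'mitigation': 'red', 'nutrition_security': 'red'}
HT-RCP8.5 {'productivity': 'blue', 'adaptation': 'blue', 'mitigation': 'red', 'nutrition_security': 'red'}
              ratio_pct          band
nutrient
energy            115.0      adequate
protein           130.0      adequate
fat                75.0  marginal_low
...
calcium            75.0  marginal_low
iron               75.0  marginal_low
...
```

Reading this: at baseline the designed gaps (fat, calcium, iron sit at
75% of their principal requirement) are flagged and everything else is
adequate. By mid-century, low-transformation futures turn nutrition
red — population growth outpaces a static food system — while
high-transformation futures multiply production (blue productivity and
adaptation) at the cost of higher gross emissions (red mitigation).
Zambia's HT cells stay red/amber on nutrition because its cropland
expands only 5%; fat remains the binding gap.

The same run is available from the shell:

```sh
nutriscen run --seed 1 --countries Zambia --out out/
nutriscen score --scorecards out/scorecards.json
```

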