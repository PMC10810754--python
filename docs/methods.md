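# Methods

This note documents the models, parameters, numerical choices and
limitations of the package. It records how each stage works and why
the open design choices were settled the way they were; every
empirical statement here is something the test suite or
`scripts/acceptance.py` computes.

## Scenario frame

Each country's futures form a 2×2 matrix: agricultural transformation
(LT = low, HT = high) × climate risk (RCP2.6 = low, RCP8.5 = high).
A scenario cell carries the quantitative levers: arable/pasture area
change (fractions of baseline area), yield-trend mode (`full`, `half`,
`none`), adaptation mode (`autonomous`, `transformative`),
diversification direction with a maize share bound, irrigation change,
whether allocation is production-optimized, and stakeholder trade
multipliers. The analysis compares a baseline window (1990–2010,
centred on 2000) with a future window (2040–2060, centred on 2050), a
50-year horizon.

Countries are modelled as K discrete land zones (default K = 10) with
per-zone areas and yields rather than grids; protected zones carry no
expandable land, and validation rejects any cell whose requested
arable-plus-pasture expansion exceeds total expandable land. The four
packaged fixtures encode the country characterizations that are stated
qualitatively — no yield trend in Malawi/Tanzania/Zambia LT cells, the
intermediate (half) trend in every South Africa cell, Zambia HT arable
expansion of exactly 5%, Malawi/Tanzania HT expansion exhausting
expandable land (>50% arable growth), the Tanzania HT-RCP8.5 pasture
expansion at 0.5× its HT-RCP2.6 value, and reduced crop diversity in
the Tanzania/Zambia HT-RCP8.5 cells. All values that are not stated
anywhere (zone areas, irrigation changes, trade multipliers, South
Africa area changes) are flagged `assumed` inside the fixture files.

## Crop engine

Projected yield per zone, commodity and climate model:

    y' = (y + β·h) · adaptation · irrigation · climate_factor

* **Trend** `β` is the OLS slope of the national 1960–2010 yield
  series (linear is the minimal reading of "continuation of historical
  trends"); `half` mode halves it, `none` drops it. Results floor at 0.
* **Adaptation**: autonomous = (1 + 0.05) × (1 − 0.05 penalty) ≈ 1.0;
  transformative = 1 + 0.10 and cancels the growing-season-loss
  penalty. Defaults are deliberately small so that HT gains come
  mainly from the trend, area and allocation levers; whether trend and
  adaptation compound is genuinely open, and exposing both levers with
  near-neutral adaptation defaults keeps them separable. Validation
  enforces autonomous ≤ transformative.
* **Irrigation** enters as `1 + Δirr · irrigable_fraction (0.2) ·
  yield_boost (0.5)` — no irrigation formula is given anywhere, so a
  configured multiplier on a configured irrigable fraction is used.
* **Climate factors** are multiplicative (preserving non-negativity),
  log-normal with log-scale dispersion σ = 0.05 (RCP2.6) or 0.15
  (RCP8.5) and median exp(−0.5σ), so the high-risk ensemble is wider
  and more adverse; σ = 0 gives unit factors exactly.

**Allocation.** HT cells solve a continuous LP (areas, not integer
assignments): maximize national production subject to zone areas and
national share bounds. Increased diversification caps every crop
(including maize) at the scenario's share bound and floors each crop
at half its baseline share, spreading area across more crops;
decreased diversification floors maize at the bound; otherwise mild
floors (¼ of baseline shares) keep continuity with the baseline mix.
LT cells skip the LP and rescale baseline area shares. Expansion is
distributed over zones in proportion to expandable land, so protected
zones never grow.

Numerical choices: the LP runs on HiGHS; a vanishing (1e-9-scaled)
lexicographic perturbation over (commodity, zone) makes tie-breaking
deterministic. Optimality is verified in tests against an exhaustive
oracle: with integer zone areas and integer share-bound right-hand
sides the constraint matrix is totally unimodular (transportation
structure), so the continuous optimum equals the best integer
allocation, which is enumerable for small instances (≤4 zones × ≤3
crops × ≤3 area units; 100 instances run in seconds).

## Livestock engine

Seven categories; three feed streams (pasture, residues, feed crops)
with fixed category allocation shares (reallocation between categories
is not modelled; shares are overridable). Baseline feed-to-output
ratios (t output per t allocated feed) are fitted once and held to
2050, making projection homogeneous of degree 1 in the feed basket.
The future basket takes pasture × (1 + pasture area change), residues
as configured fractions of projected crop production (0.3 for cereals,
0 otherwise — stream named but unquantified in the source material)
and feed crops from the feed use-shares of projected production.
Because the future feed-crop stream is computed from the same shares
the balance sheet uses, feed demand and the feed column are consistent
by construction.

## Food accounts

The balance identity `food = production + imports − exports − Δstock −
feed − seed − losses` is asserted (not assumed) after every operation.
Future stock change is fixed at 0; non-food uses scale with production
via baseline shares, mirroring the business-as-usual proportionality
principle. Vignettes: self-sufficiency zeroes trade (idempotent);
business-as-usual applies baseline trade-to-production ratios to
future production (exactly recomputable); stakeholder scales the
baseline-proportional flows by the scenario's expert multipliers
(applying them to BAU-projected flows was the other defensible
reading; proportional-then-scale is used and documented here). Two
guard rails: a commodity with zero baseline production but nonzero
baseline trade holds its absolute baseline flows (logged), and if a
stakeholder export multiplier would drive food negative, exports are
capped at availability (logged) — BAU and self-sufficiency never need
the cap, so their exactness contracts are unaffected.

## Nutrition

Supply per capita per day:

    supply_n = Σ_c food_c · 10⁴ · Σ_i w_i·e_i·(1−h_i)·d_{i,n} / pop / 365

with item weights `w` (sum to 1 per commodity, held at baseline),
edible fraction `e`, household-waste fraction `h` and densities `d`
per 100 g edible portion. Tracked nutrients: energy (kcal), protein,
fat, carbohydrate, saturated fat, fibre (g), calcium, zinc, iron,
vitamin C, thiamin, riboflavin, niacin, vitamin B6 (mg), folate (µg);
vitamin A (retinol activity equivalents) is optional. Saturated fat is
tracked in supply but carries no adequacy band; protein uses the
standard LRNI/EAR/RNI band.

Requirements are population-weighted means of per-group (age–sex)
thresholds, strictly increasing per group. Band boundaries are
lower-closed ([EAR, RNI) is marginal-high; supply exactly at a
threshold lands in the higher band) — the convention is not stated
anywhere, so it is fixed here and tested. The reported ratio is
100 × supply / principal target, where the principal is the RNI for
band-1 nutrients and the middle threshold (average energy requirement,
fat min–max midpoint) for energy and fat, which puts "requirement" at
100% with symmetric marginal bands. Packaged per-group reference
values are synthetic placeholders calibrated by the generator (below);
real WHO-style values can be supplied as CSV.

## Climate smartness

Gross emissions = Σ crop production × crop EF (default 0.35 t CO₂e/t)
+ Σ livestock output × category EF (3–30 t CO₂e/t) + expanded area ×
LUC EF (100 t CO₂e/ha). The SOC term is a declared linear surrogate —
soc_delta = 0.05 t CO₂e per tonne of organic input, with organic input
= crop production × 0.3 residue return — not a claim of process-model
equivalence; all factors are overridable and flagged as assumed
values. The ledger identity `net = gross − soc_delta` is asserted on
every output. A yield shock is a year strictly below 0.5× the baseline
mean yield ("approximately half" needs an operational cut; strict
inequality at exactly half is documented and tested).

## Scoring

Rules live in a versioned YAML (`config/scoring_rules.yaml`), not in
code, because the published cut-offs are not in the main text; the
defaults are: productivity blue at median cross-model production
change ≥ +10%, red at ≤ −5%; adaptation judged on the worst climate
model (blue ≥ 0%, red < −5%) — a resilience reading; mitigation blue
when median net emissions do not rise, amber when SOC offsets ≥ 50% of
the gross rise, red otherwise. Nutrition security: blue if at least
one trade vignette meets the principal target for every nutrient
(median across models), red if some nutrient sits below its
"clearly-below" line in every vignette — the EAR for band-1 nutrients
and the minimum intake for fat/energy (whose principal *is* the mid
threshold) — amber otherwise. Stars follow the strict definitions
(every model improving; every requirement met in every vignette) and
structurally require a blue verdict. Statement confidence: high =
unanimous cross-model sign agreement, medium ≥ 4/5, low otherwise
(three levels; the source scale is not enumerated).

## Synthetic-data generator

The generator emulates the statistical structure of the real inputs:
20 commodities spanning cereal / root / fruit / vegetable / pulse /
oil / sugar classes (up to 96 supported) with maize-dominated
Dirichlet area mixes; log-normal yields around class-typical levels;
1960–2010 yield histories with relative trends of 2–4 %/yr of baseline
yield (a full-trend 50-year horizon then yields ≈100–200% gains, mean
≈150% — `mean_ht_yield_increase_pct` in the acceptance output);
Dirichlet item weights; five named climate models; eight age–sex
demographic groups with log-normal requirement heterogeneity; and
per-crop shock rates (maize 0.10/yr > default 0.05 > soybean 0.03).
Country populations use order-of-magnitude realistic sizes (10–45 M)
with mid-century growth ratios of 1.35 (South Africa) to 2.1 (Zambia).
All draws come from one RNG keyed by (seed, table name): adding a
table never perturbs the others, and a fixed seed gives byte-identical
bundles.

**Designed gaps.** Rather than tuning compositions, the generator
calibrates per-group requirement values so the population-weighted
principal threshold makes baseline supply land at exactly 75% of
requirement for gap nutrients (fat, calcium, iron by default), 130%
for the rest and 115% of the average energy requirement — so baseline
adequacy verdicts match the designed gaps identically for every seed
(verified over a 20-seed sweep). Group heterogeneity is normalized to
a weighted mean of exactly 1 at baseline; the 2050 requirement shifts
with the demographic mix.

What the generator does *not* emulate: real country magnitudes beyond
order of magnitude, within-year price or demand dynamics, bilateral
trade structure, spatially correlated climate impacts, or actual WHO
reference values. Passing tests therefore demonstrate that the
*machinery* — accounting identities, optimization, classification,
scoring — behaves correctly under realistic structure, not that any
country-specific number is predicted.

## Problem sizes

The default study configuration is 20 commodities × 10 zones × 5
climate models × 3 trade vignettes × 16 scenarios (4 countries); a
full assessment runs in a few seconds on one CPU and is bit-identical
under a fixed seed. Oracle comparisons use ≤4 zones × ≤3 crops with
integer areas ≤3 units; shock statistics use 10,000-year series;
account contracts use 1,000 random balances.

## Limitations

No process-based crop or soil modelling (climate impacts and SOC are
exogenous surrogates); no herd demography or animal energetics; no
prices, production costs, tariffs or bilateral partners; no
intra-population food access or distribution, bioavailability, or
individual diets; expert implication statements are templated, not
authored. The scoring cut-offs and all emission factors are declared
assumptions intended to be overridden with country-specific values.
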