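# South Africa scenario fixture.
# Transformation axis: extent of land reform.
# Text-stated values: every cell uses the intermediate (half) yield
# trend; high-climate-risk cells carry greater adaptation investment
# (new varieties, irrigation expansion, crop diversification).  Zone
# areas, area changes and trade multipliers are assumed.
schema_version: 1
country: South Africa
assumed: [zones, arable_area_change, pasture_area_change, irrigation_change, trade_vignette_params]
baseline_year_window: [1990, 2010]
future_year_window: [2040, 2060]
zones:
  - {arable_ha: 1400000, pasture_ha: 9000000, expandable_ha: 150000}
  - {arable_ha: 1300000, pasture_ha: 8500000, expandable_ha: 150000}
  - {arable_ha: 1300000, pasture_ha: 8500000, expandable_ha: 150000}
  - {arable_ha: 1250000, pasture_ha: 8000000, expandable_ha: 150000}
  - {arable_ha: 1200000, pasture_ha: 8000000, expandable_ha: 150000}
  - {arable_ha: 1200000, pasture_ha: 8000000, expandable_ha: 150000}
  - {arable_ha: 1150000, pasture_ha: 8000000, expandable_ha: 150000}
  - {arable_ha: 1100000, pasture_ha: 7500000, expandable_ha: 150000}
  - {arable_ha: 1050000, pasture_ha: 7500000, expandable_ha: 0, protected: true}
  - {arable_ha: 1050000, pasture_ha: 7000000, expandable_ha: 0, protected: true}
cells:
  LT-RCP2.6:
    arable_area_change: 0.0
    pasture_area_change: 0.0
    yield_trend_mode: half
    adaptation_mode: autonomous
    diversification: none
    maize_share_bound: 1.0
    irrigation_change: 0.0
    optimize_allocation: false
    trade_vignette_params: {import_multiplier: 0.9, export_multiplier: 1.1}
    assumed: [trade_vignette_params]
  LT-RCP8.5:
    arable_area_change: 0.0
    pasture_area_change: 0.0
    yield_trend_mode: half
    adaptation_mode: transformative
    diversification: increase
    maize_share_bound: 0.35
    irrigation_change: 0.3
    optimize_allocation: false
    trade_vignette_params: {import_multiplier: 2.0, export_multiplier: 0.5}
    assumed: [maize_share_bound, irrigation_change, trade_vignette_params]
  HT-RCP2.6:
    arable_area_change: 0.05
    pasture_area_change: 0.0
    yield_trend_mode: half
    adaptation_mode: transformative
    diversification: none
    maize_share_bound: 1.0
    irrigation_change: 0.1
    optimize_allocation: false
    trade_vignette_params: {import_multiplier: 0.8, export_multiplier: 1.2}
    assumed: [arable_area_change, irrigation_change, trade_vignette_params]
  HT-RCP8.5:
    arable_area_change: 0.05
    pasture_area_change: 0.0
    yield_trend_mode: half
    adaptation_mode: transformative
    diversification: increase
    maize_share_bound: 0.35
    irrigation_change: 0.3
    optimize_allocation: false
    trade_vignette_params: {import_multiplier: 2.0, export_multiplier: 0.5}
    assumed: [arable_area_change, maize_share_bound, irrigation_change, trade_vignette_params]
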