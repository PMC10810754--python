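# Malawi scenario fixture.
# Transformation axis: effectiveness of policy implementation.
# Text-stated values: LT cells carry no yield trend; HT arable expansion
# exhausts expandable land (arable land expands by over 50%).  Zone
# areas, pasture changes, irrigation and trade multipliers are assumed.
schema_version: 1
country: Malawi
assumed: [zones, pasture_area_change, irrigation_change, trade_vignette_params]
baseline_year_window: [1990, 2010]
future_year_window: [2040, 2060]
zones:
  - {arable_ha: 500000, pasture_ha: 200000, expandable_ha: 400000}
  - {arable_ha: 450000, pasture_ha: 150000, expandable_ha: 390000}
  - {arable_ha: 420000, pasture_ha: 200000, expandable_ha: 380000}
  - {arable_ha: 400000, pasture_ha: 180000, expandable_ha: 370000}
  - {arable_ha: 380000, pasture_ha: 170000, expandable_ha: 370000}
  - {arable_ha: 390000, pasture_ha: 160000, expandable_ha: 370000}
  - {arable_ha: 360000, pasture_ha: 200000, expandable_ha: 360000}
  - {arable_ha: 350000, pasture_ha: 240000, expandable_ha: 350000}
  - {arable_ha: 280000, pasture_ha: 150000, expandable_ha: 0, protected: true}
  - {arable_ha: 270000, pasture_ha: 150000, expandable_ha: 0, protected: true}
cells:
  LT-RCP2.6:
    arable_area_change: 0.0
    pasture_area_change: 0.0
    yield_trend_mode: none
    adaptation_mode: autonomous
    diversification: none
    maize_share_bound: 1.0
    irrigation_change: 0.0
    optimize_allocation: false
    trade_vignette_params: {import_multiplier: 2.0, export_multiplier: 0.5}
    assumed: [trade_vignette_params]
  LT-RCP8.5:
    arable_area_change: 0.0
    pasture_area_change: 0.0
    yield_trend_mode: none
    adaptation_mode: autonomous
    diversification: none
    maize_share_bound: 1.0
    irrigation_change: 0.0
    optimize_allocation: false
    trade_vignette_params: {import_multiplier: 2.0, export_multiplier: 0.5}
    assumed: [trade_vignette_params]
  HT-RCP2.6:
    arable_area_change: 0.55
    pasture_area_change: 0.5
    yield_trend_mode: full
    adaptation_mode: transformative
    diversification: increase
    maize_share_bound: 0.3
    irrigation_change: 0.3
    optimize_allocation: true
    trade_vignette_params: {import_multiplier: 0.8, export_multiplier: 1.5}
    assumed: [pasture_area_change, irrigation_change, maize_share_bound, trade_vignette_params]
  HT-RCP8.5:
    arable_area_change: 0.55
    pasture_area_change: 0.5
    yield_trend_mode: full
    adaptation_mode: transformative
    diversification: increase
    maize_share_bound: 0.3
    irrigation_change: 0.3
    optimize_allocation: true
    trade_vignette_params: {import_multiplier: 2.0, export_multiplier: 0.5}
    assumed: [pasture_area_change, irrigation_change, maize_share_bound, trade_vignette_params]
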