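# Tanzania scenario fixture.
# Transformation axis: extent of technological transformation.
# Text-stated values: LT cells carry no yield trend; HT area expansion
# exhausts expandable land except HT-RCP8.5, where livestock expansion
# is smaller (encoded as 0.5x the HT-RCP2.6 pasture expansion);
# HT-RCP8.5 reduces crop diversity, HT-RCP2.6 increases it.
schema_version: 1
country: Tanzania
assumed: [zones, irrigation_change, trade_vignette_params]
baseline_year_window: [1990, 2010]
future_year_window: [2040, 2060]
zones:
  - {arable_ha: 1600000, pasture_ha: 3000000, expandable_ha: 3000000}
  - {arable_ha: 1500000, pasture_ha: 2800000, expandable_ha: 2900000}
  - {arable_ha: 1500000, pasture_ha: 2600000, expandable_ha: 2900000}
  - {arable_ha: 1400000, pasture_ha: 2600000, expandable_ha: 2800000}
  - {arable_ha: 1400000, pasture_ha: 2400000, expandable_ha: 2800000}
  - {arable_ha: 1300000, pasture_ha: 2400000, expandable_ha: 2700000}
  - {arable_ha: 1300000, pasture_ha: 2200000, expandable_ha: 2700000}
  - {arable_ha: 1200000, pasture_ha: 2000000, expandable_ha: 2700000}
  - {arable_ha: 1200000, pasture_ha: 2000000, expandable_ha: 0, protected: true}
  - {arable_ha: 1100000, pasture_ha: 2000000, expandable_ha: 0, protected: true}
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
    trade_vignette_params: {import_multiplier: 0.9, export_multiplier: 1.1}
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
    arable_area_change: 0.6
    pasture_area_change: 0.6
    yield_trend_mode: full
    adaptation_mode: transformative
    diversification: increase
    maize_share_bound: 0.3
    irrigation_change: 0.3
    optimize_allocation: true
    trade_vignette_params: {import_multiplier: 0.8, export_multiplier: 1.5}
    assumed: [irrigation_change, maize_share_bound, trade_vignette_params]
  HT-RCP8.5:
    arable_area_change: 0.6
    pasture_area_change: 0.3
    yield_trend_mode: full
    adaptation_mode: transformative
    diversification: decrease
    maize_share_bound: 0.5
    irrigation_change: 0.3
    optimize_allocation: true
    trade_vignette_params: {import_multiplier: 2.0, export_multiplier: 0.5}
    assumed: [irrigation_change, maize_share_bound, trade_vignette_params]
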