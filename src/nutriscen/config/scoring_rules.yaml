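# Versioned scorecard rule thresholds.  The published scoring system's
# exact cut-offs live in supplementary material we do not reproduce;
# these defaults are declared assumptions and fully user-overridable.
rules_version: 1
# Productivity: median cross-model relative production change vs baseline.
productivity_blue: 0.10   # blue at or above +10%
productivity_red: -0.05   # red at or below -5%
# Adaptation: worst-case (minimum) cross-model relative production change.
adaptation_blue: 0.0
adaptation_red: -0.05
# Mitigation: median net-emission change vs baseline; amber if SOC
# sequestration offsets at least this fraction of the gross increase.
mitigation_offset_fraction: 0.5
# Nutrition ratios are percentages of the principal requirement.
nutrition_target_pct: 100.0
# Calibrated-statement confidence: high needs unanimous cross-model
# sign agreement; medium needs at least this fraction.
confidence_medium_fraction: 0.8
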