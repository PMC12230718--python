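# Default penalty configuration for IRE quality scoring.
# Score = base_score - sum of applicable penalties; scale is (-inf, 8].
# All values overridable via a user config file with the same keys.
base_score: 8.0
upper_stem_mismatch: 1.5
upper_stem_bulge: 1.5
upper_stem_wobble: 0.5
noncanonical_motif: 1.0
n7_n25_mismatch: 3.0
n7_n25_wobble: 1.5
discordance_weight: 2.5     # penalty = weight * (1 - concordance)
nonnegative_dg: 2.0         # applied when the folded window has delta_g >= 0
# Motif families exempt from the noncanonical-motif penalty (experimentally
# validated loop classes).
canonical_families: ["1", "2", "19"]
# Category cut-points, scanned High -> Low; score >= threshold selects the
# category. Anything below the last threshold is Very-low.
thresholds:
  High: 7.0
  High-medium: 6.0
  Medium: 5.0
  Medium-low: 3.5
  Low: 1.5
# Display-bar clamps for the score bar ([bar_min, 8]) and the energy bar
# ([energy_min, 0], kcal/mol).
bar_min: -4.0
energy_min: -12.0
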