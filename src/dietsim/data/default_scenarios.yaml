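# Default scenario configuration: the primary parameter sets plus the
# lower/upper sensitivity bounds for each family.
#
# replacement_ratios: grams of replacement added per gram of discretionary
# item removed.  A scalar applies everywhere; a mapping may list 3-digit
# subgroup codes with a "default" fallback.  The overall population value
# derived from median consumption-line grams is 1.29.
scenarios:
  moderation_primary:
    family: moderation
    target: all
    reduction_fraction: 0.5
    compensation_fraction: 0.0
  moderation_comp25:
    family: moderation
    target: all
    reduction_fraction: 0.5
    compensation_fraction: 0.25
  moderation_comp75:
    family: moderation
    target: all
    reduction_fraction: 0.5
    compensation_fraction: 0.75
  substitution_all_core:
    family: substitution
    target: all
    reduction_fraction: 0.5
    substitution_pool: all_core
    replacement_ratios: 1.29
  substitution_fruit_veg:
    family: substitution
    target: all
    reduction_fraction: 0.5
    substitution_pool: fruit_veg_only
    replacement_ratios: 1.29
  reformulation_lower:
    family: reformulation
    target: all
    reformulation:
      sfa_replace_fraction: 0.25
      added_sugar_reduction: 0.10
      sodium_reduction: 0.10
      alcohol_reduction: 0.25
  reformulation_primary:
    family: reformulation
    target: all
    reformulation:
      sfa_replace_fraction: 0.50
      added_sugar_reduction: 0.25
      sodium_reduction: 0.20
      alcohol_reduction: 0.25
  reformulation_upper:
    family: reformulation
    target: all
    reformulation:
      sfa_replace_fraction: 0.75
      added_sugar_reduction: 0.40
      sodium_reduction: 0.40
      alcohol_reduction: 0.50
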