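# Default conversion rulesets for the synthetic cohorts' raw-unit styles.
#
# Target units (shared across cohorts):
#   height              m
#   moderate_activity   h/week
#   vigorous_activity   h/week
#   tv_time             h/week
#   smoker_status       binary (smoker / non_smoker)
#
# The "wh" style already records everything in target units (prospective
# harmonisation); the "ukb" style needs rescaling, field combination and
# categorical collapsing (retrospective harmonisation).

wh:
  variables:
    height:
      kind: passthrough
      target_unit: m
      source_unit: m
    moderate_activity:
      kind: passthrough
      target_unit: h/week
      source_unit: h/week
    vigorous_activity:
      kind: passthrough
      target_unit: h/week
      source_unit: h/week
    tv_time:
      kind: passthrough
      target_unit: h/week
      source_unit: h/week
    smoker_status:
      kind: categorical_collapse
      target_unit: binary
      source_unit: binary
      mapping:
        smoker: smoker
        non_smoker: non_smoker

ukb:
  variables:
    height:
      kind: linear_rescale
      scale: 0.01
      target_unit: m
      source_unit: cm
    moderate_activity:
      # day/week x min/day -> h/week
      kind: combine_fields
      fields: [moderate_activity_days_week, moderate_activity_min_day]
      combiner: product
      scale: 0.016666666666666666
      target_unit: h/week
    vigorous_activity:
      # min/day -> h/week: x 7/60
      kind: linear_rescale
      source_field: vigorous_activity_min_day
      scale: 0.11666666666666667
      target_unit: h/week
      source_unit: min/day
    tv_time:
      # h/day -> h/week
      kind: linear_rescale
      source_field: tv_time_h_day
      scale: 7.0
      target_unit: h/week
      source_unit: h/day
    smoker_status:
      kind: categorical_collapse
      target_unit: binary
      source_unit: 4-class
      mapping:
        current: smoker
        previous: non_smoker
        never: non_smoker
        prefer_not: non_smoker
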