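# Default per-element-type Environmental Risk Surface parameters.
#
# PLACEHOLDER VALUES: these intensities (I0, dimensionless interference
# units) and maximum influence distances (meters) are plausible defaults for
# synthetic experiments, not field-calibrated constants. Override any entry
# from the element attributes or a user-supplied YAML.
village:
  intensity: 10.0
  max_distance: 1500.0
  decay: linear
factory:
  intensity: 8.0
  max_distance: 1000.0
  decay: linear
road:
  intensity: 6.0
  max_distance: 800.0
  decay: linear
artificial_forest:
  intensity: 4.0
  max_distance: 500.0
  decay: linear
economic_forest:
  intensity: 3.0
  max_distance: 500.0
  decay: linear
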