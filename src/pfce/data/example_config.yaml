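# Example run configuration.
#
# `source: paper` evaluates the packaged fixture tables (two trial years,
# seven tabled indicators).  Switch to `source: synthetic` to evaluate a
# generated factorial trial with the same factor levels (300/500/700 °C ×
# 10/20/30 t/ha + control) and known ground truth.
source: paper
years: ["2023", "2024"]

# synthetic-source options (ignored for source: paper)
synthetic:
  seed: 0
  noise_scale: 1.0

# "default" uses the packaged illustrative judgment matrices (CR < 0.1).
# Override individual levels with explicit row lists, e.g.:
# judgment_matrices:
#   criteria:
#     - [1, 3, 2, 4]
#     - [0.3333333333, 1, 0.5, 2]
#     - [0.5, 2, 1, 3]
#     - [0.25, 0.5, 0.3333333333, 1]
judgment_matrices: default
equal_criteria: false

# "quantile" derives grade thresholds C1..C5 from the observed data at the
# levels below; or give a YAML path with explicit per-indicator thresholds.
grade_scheme: quantile
quantile_levels: [0.9, 0.7, 0.5, 0.3, 0.1]

combination:
  negative_alpha_policy: fallback_equal  # or absolute_normalize

surface:
  bounds:
    temperature: [300.0, 700.0]
    rate: [10.0, 30.0]
  include_control: false
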