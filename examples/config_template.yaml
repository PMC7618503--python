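# Run configuration template for the tempmort pipeline.
# All keys optional; defaults shown. Flat key-value YAML.

# municipality -> region assignment; empty means one pooled region
region_map: {}
# analysis window [start, end], ISO dates; null = span of the data
window: null

# distributed-lag settings
max_lag: 21            # days; main analysis
sensitivity_lag: 6     # days; shorter-lag sensitivity rerun
lag_knots: 3           # natural-spline knots on the log(lag+1) axis

# exposure-spline candidates: knot placements as percentiles of the
# regional temperature distribution, compared by qAIC per region
knot_candidates:
  - [0.10, 0.75, 0.90]
  - [0.25, 0.50, 0.75]
  - [0.10, 0.50, 0.90]
  - [0.50, 0.90]

# RR contrast percentiles of the regional temperature distribution
cold_percentile: 0.01
heat_percentile: 0.99

# MMT search window (percentiles) and fallback rule when the curve minimum
# sits at the upper bound: "national" (regional temperature at the national
# MMT's percentile rank), a number in (0,1), or null (report the boundary)
mmt_search: [0.01, 0.99]
mmt_fallback: national

# effect-modification settings
subgroups: []            # e.g. [sex, age_group, race]
subgroup_min_events: 100 # skip thinner subgroup series, with a log entry

alpha: 0.05          # CI level = 1 - alpha
curve_points: 200    # grid resolution of exported curves
seed: 0
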