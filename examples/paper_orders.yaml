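# Example end-to-end configuration with caller-fixed ARIMA orders
# (3,4,7) for the high-demand segment and (2,2,3) for the low-demand
# segment.  These heavily parameterized orders are an illustration of
# fixed-order analysis on short segments — expect a small-sample warning;
# the default (omit `orders`) is automatic AIC-grid selection.
protocol:
  program_length: 52
  high_demand_interval: 2
  low_demand_interval: 4
  stabilization_threshold: 4
  split_week: 27
simulation:
  n_patients: 312
  p_positive_high: 0.3
  p_positive_low: 0.15
  p_missed: 0.2
  p_dropout_per_occasion: 0.005
analysis:
  split_week: 27
  fill_policy: zero
  orders:
    - [3, 4, 7]
    - [2, 2, 3]
  forecast_horizon: 8
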