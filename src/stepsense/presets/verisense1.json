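{
  "peak_win_samples": 3,
  "min_period_samples": 5,
  "max_period_samples": 15,
  "similarity_threshold_g": -0.5,
  "continuity_window_samples": 4,
  "continuity_count_threshold": 4,
  "variance_threshold_g2": 0.001,
  "magnitude_threshold_g": 1.2,
  "algorithm_rate_hz": 15.0,
  "name": "verisense1"
}
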