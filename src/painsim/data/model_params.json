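{
  "baseline_curve": {
    "1": [[0, 7.0], [6, 6.4], [12, 6.8], [24, 6.2]],
    "2": [[0, 6.0], [6, 5.4], [12, 5.8], [24, 5.2]],
    "3": [[0, 5.0], [6, 4.4], [12, 4.8], [24, 4.2]]
  },
  "relief_cap": 8.0,
  "relaxation_rate": 0.02,
  "dt": 5,
  "min_mobility": 0.2,
  "immobility_threshold": 9.0
}
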