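{
  "name": "pak_ppm",
  "kind": "multiple_choice",
  "scale_min": 0,
  "scale_max": 1,
  "n_options": 6,
  "subscales": {
    "pain_after_surgery": "proportion_correct",
    "medications_dosages": "proportion_correct",
    "strategies": "proportion_correct",
    "side_effects": "proportion_correct",
    "problems": "proportion_correct"
  },
  "items": [
    {"id": "k1", "subscale": "pain_after_surgery", "correct": 2},
    {"id": "k2", "subscale": "pain_after_surgery", "correct": 4},
    {"id": "k3", "subscale": "medications_dosages", "correct": 1},
    {"id": "k4", "subscale": "medications_dosages", "correct": 3},
    {"id": "k5", "subscale": "medications_dosages", "correct": 5},
    {"id": "k6", "subscale": "medications_dosages", "correct": 2},
    {"id": "k7", "subscale": "medications_dosages", "correct": 4},
    {"id": "k8", "subscale": "medications_dosages", "correct": 1},
    {"id": "k9", "subscale": "medications_dosages", "correct": 3},
    {"id": "k10", "subscale": "strategies", "correct": 2},
    {"id": "k11", "subscale": "strategies", "correct": 5},
    {"id": "k12", "subscale": "side_effects", "correct": 1},
    {"id": "k13", "subscale": "side_effects", "correct": 4},
    {"id": "k14", "subscale": "problems", "correct": 3},
    {"id": "k15", "subscale": "problems", "correct": 2}
  ]
}
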