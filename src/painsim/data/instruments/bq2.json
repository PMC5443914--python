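{
  "name": "bq2",
  "kind": "likert",
  "scale_min": 0,
  "scale_max": 5,
  "subscales": {
    "physiological_effects": "mean",
    "fatalism": "mean",
    "communication": "mean",
    "harmful_effects": "mean"
  },
  "items": [
    {"id": "b1", "subscale": "physiological_effects"},
    {"id": "b2", "subscale": "physiological_effects"},
    {"id": "b3", "subscale": "physiological_effects"},
    {"id": "b4", "subscale": "physiological_effects"},
    {"id": "b5", "subscale": "physiological_effects"},
    {"id": "b6", "subscale": "physiological_effects"},
    {"id": "b7", "subscale": "physiological_effects"},
    {"id": "b8", "subscale": "physiological_effects"},
    {"id": "b9", "subscale": "physiological_effects"},
    {"id": "b10", "subscale": "physiological_effects"},
    {"id": "b11", "subscale": "physiological_effects"},
    {"id": "b12", "subscale": "physiological_effects"},
    {"id": "b13", "subscale": "fatalism"},
    {"id": "b14", "subscale": "fatalism"},
    {"id": "b15", "subscale": "fatalism"},
    {"id": "b16", "subscale": "communication"},
    {"id": "b17", "subscale": "communication"},
    {"id": "b18", "subscale": "communication"},
    {"id": "b19", "subscale": "harmful_effects"},
    {"id": "b20", "subscale": "harmful_effects"},
    {"id": "b21", "subscale": "harmful_effects"},
    {"id": "b22", "subscale": "harmful_effects"},
    {"id": "b23", "subscale": "harmful_effects"},
    {"id": "b24", "subscale": "harmful_effects"},
    {"id": "b25", "subscale": "harmful_effects"},
    {"id": "b26", "subscale": "harmful_effects"},
    {"id": "b27", "subscale": "harmful_effects"}
  ]
}
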