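{
  "goals": [
    {"day_index": 1, "kind": "minimize_doses", "description": "Take as little pain medication as possible"},
    {"day_index": 2, "kind": "pain_under_threshold", "threshold": 3, "description": "Keep pain severity under 3 regardless of side effects"},
    {"day_index": 3, "kind": "pain_under_threshold", "threshold": 5, "description": "Keep pain severity under 5 the whole day"}
  ],
  "star_thresholds": {"three": 0.95, "two": 0.6},
  "dose_ceiling": 8,
  "event": {"probability": 0.3, "pain_floor": 8.0, "post_consult_pain": 5.0},
  "monologue": {
    "flavor_rate": 0.02,
    "pain_thresholds": [3.0, 5.0, 8.0],
    "flavor_messages": [
      "I wonder what's on TV?",
      "Maybe I should call my sister later.",
      "The house could use some tidying.",
      "I'm glad to be home again."
    ],
    "medication_working": "I can feel the medication working...",
    "pain_rising": "My pain is getting worse.",
    "pain_easing": "The pain is easing off."
  }
}
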