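{
  "activities": [
    {"id": "shower", "kind": "selfcare", "duration": 30, "pain_effect": 0.5, "requires_movement": true, "counts_toward_tasks": true},
    {"id": "toilet", "kind": "selfcare", "duration": 10, "pain_effect": 0.0, "requires_movement": true, "counts_toward_tasks": false},
    {"id": "cook", "kind": "chore", "duration": 45, "pain_effect": 0.5, "requires_movement": true, "counts_toward_tasks": true},
    {"id": "dishes", "kind": "chore", "duration": 20, "pain_effect": 0.5, "requires_movement": true, "counts_toward_tasks": true},
    {"id": "watch_tv", "kind": "distraction", "duration": 60, "pain_effect": -1.0, "requires_movement": false, "counts_toward_tasks": false},
    {"id": "use_computer", "kind": "distraction", "duration": 45, "pain_effect": -1.0, "requires_movement": false, "counts_toward_tasks": false},
    {"id": "rest_sofa", "kind": "rest", "duration": 60, "pain_effect": -1.5, "requires_movement": false, "counts_toward_tasks": false},
    {"id": "lie_bed", "kind": "rest", "duration": 90, "pain_effect": -2.0, "requires_movement": false, "counts_toward_tasks": false}
  ]
}
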