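{
  "medications": [
    {
      "id": "paracetamol",
      "tablet_strength": "500 mg",
      "max_tablets_per_dose": 2,
      "max_tablets_per_day": 8,
      "min_dose_interval": 240,
      "onset": 30,
      "time_to_peak": 60,
      "effect_duration": 360,
      "peak_relief": 1.5,
      "side_effect_rules": []
    },
    {
      "id": "ibuprofen",
      "tablet_strength": "400 mg",
      "max_tablets_per_dose": 1,
      "max_tablets_per_day": 3,
      "min_dose_interval": 360,
      "onset": 30,
      "time_to_peak": 90,
      "effect_duration": 480,
      "peak_relief": 2.0,
      "side_effect_rules": [
        {
          "effect_id": "stomach_irritation",
          "metric": "daily_tablets",
          "threshold": 3,
          "duration": 180
        }
      ]
    },
    {
      "id": "paracetamol_codeine",
      "tablet_strength": "500 mg + 30 mg",
      "max_tablets_per_dose": 2,
      "max_tablets_per_day": 6,
      "min_dose_interval": 240,
      "onset": 40,
      "time_to_peak": 80,
      "effect_duration": 360,
      "peak_relief": 2.5,
      "side_effect_rules": [
        {
          "effect_id": "nausea",
          "metric": "active_tablets",
          "threshold": 3,
          "duration": 240
        },
        {
          "effect_id": "constipation",
          "metric": "daily_tablets",
          "threshold": 5,
          "duration": 480
        }
      ]
    },
    {
      "id": "tramadol",
      "tablet_strength": "50 mg",
      "max_tablets_per_dose": 2,
      "max_tablets_per_day": 8,
      "min_dose_interval": 300,
      "onset": 45,
      "time_to_peak": 120,
      "effect_duration": 420,
      "peak_relief": 3.0,
      "side_effect_rules": [
        {
          "effect_id": "drowsiness",
          "metric": "active_tablets",
          "threshold": 3,
          "duration": 240
        },
        {
          "effect_id": "nausea",
          "metric": "daily_tablets",
          "threshold": 6,
          "duration": 240
        }
      ]
    }
  ]
}
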