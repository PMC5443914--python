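{
  "name": "pop_mgs",
  "kind": "likert",
  "scale_min": 0,
  "scale_max": 5,
  "subscales": {"ease_of_use": "mean", "usefulness": "mean"},
  "items": [
    {"id": "p1", "subscale": "ease_of_use", "left": "The game was easy to learn"},
    {"id": "p2", "subscale": "ease_of_use", "left": "Controlling the avatar was easy"},
    {"id": "p3", "subscale": "ease_of_use", "left": "The interface was easy to understand"},
    {"id": "p4", "subscale": "ease_of_use", "left": "I always knew what to do next"},
    {"id": "p5", "subscale": "ease_of_use", "left": "I did not have any technical problems using the game"},
    {"id": "p6", "subscale": "ease_of_use", "left": "The text in the game was easy to read"},
    {"id": "p7", "subscale": "usefulness", "left": "The game taught me about pain medication"},
    {"id": "p8", "subscale": "usefulness", "left": "The game taught me about pain management strategies"},
    {"id": "p9", "subscale": "usefulness", "left": "The feedback helped me understand my decisions"},
    {"id": "p10", "subscale": "usefulness", "left": "The after-action review was informative"},
    {"id": "p11", "subscale": "usefulness", "left": "I would recommend the game to surgical patients"},
    {"id": "p12", "subscale": "usefulness", "left": "Playing the game was a useful way to learn"}
  ]
}
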