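{
  "name": "attrakdiff2",
  "kind": "semantic_differential",
  "scale_min": 1,
  "scale_max": 7,
  "subscales": {"PQ": "mean", "HQI": "mean", "HQS": "mean", "ATT": "mean"},
  "items": [
    {"id": "pq1", "subscale": "PQ", "reverse": true, "left": "human", "right": "technical"},
    {"id": "pq2", "subscale": "PQ", "reverse": false, "left": "complicated", "right": "simple"},
    {"id": "pq3", "subscale": "PQ", "reverse": false, "left": "impractical", "right": "practical"},
    {"id": "pq4", "subscale": "PQ", "reverse": false, "left": "cumbersome", "right": "straightforward"},
    {"id": "pq5", "subscale": "PQ", "reverse": true, "left": "predictable", "right": "unpredictable"},
    {"id": "pq6", "subscale": "PQ", "reverse": false, "left": "confusing", "right": "clearly structured"},
    {"id": "pq7", "subscale": "PQ", "reverse": false, "left": "unruly", "right": "manageable"},
    {"id": "hqi1", "subscale": "HQI", "reverse": false, "left": "isolating", "right": "connective"},
    {"id": "hqi2", "subscale": "HQI", "reverse": true, "left": "professional", "right": "unprofessional"},
    {"id": "hqi3", "subscale": "HQI", "reverse": false, "left": "tacky", "right": "stylish"},
    {"id": "hqi4", "subscale": "HQI", "reverse": false, "left": "cheap", "right": "premium"},
    {"id": "hqi5", "subscale": "HQI", "reverse": false, "left": "alienating", "right": "integrating"},
    {"id": "hqi6", "subscale": "HQI", "reverse": false, "left": "separates me from people", "right": "brings me closer to people"},
    {"id": "hqi7", "subscale": "HQI", "reverse": false, "left": "unpresentable", "right": "presentable"},
    {"id": "hqs1", "subscale": "HQS", "reverse": false, "left": "conventional", "right": "inventive"},
    {"id": "hqs2", "subscale": "HQS", "reverse": false, "left": "unimaginative", "right": "creative"},
    {"id": "hqs3", "subscale": "HQS", "reverse": true, "left": "bold", "right": "cautious"},
    {"id": "hqs4", "subscale": "HQS", "reverse": false, "left": "conservative", "right": "innovative"},
    {"id": "hqs5", "subscale": "HQS", "reverse": false, "left": "dull", "right": "captivating"},
    {"id": "hqs6", "subscale": "HQS", "reverse": false, "left": "undemanding", "right": "challenging"},
    {"id": "hqs7", "subscale": "HQS", "reverse": false, "left": "ordinary", "right": "novel"},
    {"id": "att1", "subscale": "ATT", "reverse": false, "left": "unpleasant", "right": "pleasant"},
    {"id": "att2", "subscale": "ATT", "reverse": true, "left": "attractive", "right": "ugly"},
    {"id": "att3", "subscale": "ATT", "reverse": false, "left": "disagreeable", "right": "likeable"},
    {"id": "att4", "subscale": "ATT", "reverse": false, "left": "rejecting", "right": "inviting"},
    {"id": "att5", "subscale": "ATT", "reverse": false, "left": "bad", "right": "good"},
    {"id": "att6", "subscale": "ATT", "reverse": false, "left": "repelling", "right": "appealing"},
    {"id": "att7", "subscale": "ATT", "reverse": false, "left": "discouraging", "right": "motivating"}
  ]
}
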