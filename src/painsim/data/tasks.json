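{
  "tasks_by_day": {
    "1": ["shower", "dishes"],
    "2": ["shower", "cook", "dishes"],
    "3": ["shower", "cook", "dishes"]
  }
}
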