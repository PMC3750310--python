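{
  "comment": "Per-food extreme-P90 exposure overrides (ug/day) for foods whose P90 concentration is not reported.",
  "tuber": 0.10
}
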