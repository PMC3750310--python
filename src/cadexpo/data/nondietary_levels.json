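{
  "comment": "Survey-derived per-level exposures (ug/day) for the non-dietary sources; the smoking levels and the upper water cells come from individual-level survey data and cannot be recomputed from the shipped summary tables.",
  "water": {"mean": 0.03, "median": 0.03, "p90": 0.05, "extreme_p90": 0.05},
  "smoking": {"mean": 3.93, "median": 0.0, "p90": 16.15, "extreme_p90": 16.39}
}
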