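{
  "description": "HbA1c (index, >=5.7%) vs OGTT abnormal glucose tolerance (reference) 2x2 counts by G6PD status, as observed in the Africans in America cohort (n=521 evaluable participants).",
  "strata": [
    {"stratum": "DEFICIENT", "tp": 0, "fp": 0, "tn": 37, "fn": 17},
    {"stratum": "NORMAL", "tp": 98, "fp": 55, "tn": 217, "fn": 97}
  ]
}
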