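# Desk-scale configuration: 6 subjects per group, 2-minute resting period.
seed: 0
cohort:
  n_control: 6
  n_tinnitus: 6
  severity_counts: [4, 2]
  schedule:
    resting_duration_s: 120.0
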