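# Three-group synfire filter (45 RS + 18 FS per group)
experiment: synfire_filter
mode: ideal
seeds: {chip: 0, trial: 0}
params:
  a: 1
  sigma: 0.5
  T_ms: 150
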