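# Synfire chain with feedforward inhibition, original-size groups
experiment: synfire
mode: ideal
seeds: {chip: 0, trial: 0}
params:
  n_groups: 4
  a: 1
  sigma: 1.0
  T_ms: 150
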