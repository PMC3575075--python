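# Balanced random network: asynchronous irregular state, CV ~ 1, CC ~ 0
experiment: brn
mode: ideal
seeds: {chip: 0, trial: 0}
params:
  T_ms: 20000
  target_rate: 9.0
  n_pairs: 1000
  bin_ms: 2.0
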