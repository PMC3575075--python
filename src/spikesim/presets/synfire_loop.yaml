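# Closed synfire loop on one 192-neuron chip; self-sustained propagation
experiment: synfire_loop
mode: ideal
seeds: {chip: 0, trial: 0}
params:
  a: 1
  sigma: 0.5
  T_ms: 2000
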