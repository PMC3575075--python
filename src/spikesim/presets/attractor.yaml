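# Cortical layer 2/3 attractor memory, scaled to 188 neurons
experiment: attractor
mode: ideal
seeds: {chip: 0, trial: 0}
params:
  T_ms: 5000
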