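# Antennal-lobe channel decorrelation: q sweep over lateral inhibition
experiment: al
mode: ideal
seeds: {chip: 0, trial: 0}
params:
  n_patterns: 100
  target_corr: 0.6
  duration_ms: 1000
  q_values: [0.0, 0.25, 0.5, 0.75, 1.0]
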