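# Soft winner-take-all ring: half-ring rate curves cross at r2 = r1
experiment: swta
mode: ideal
seeds: {chip: 0, trial: 0}
params:
  r1: 50.0
  r2_values: [0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
  n_runs: 10
  T_ms: 2000
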