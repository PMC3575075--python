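# Liquid state machine + tempotron readout, one-window-back classification
experiment: lsm
mode: ideal
seeds: {chip: 0, trial: 0}
params:
  n_train: 1000
  n_eval: 200
  lag: 1
  jitter_sd: 1.0
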