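# Desk-scale pipeline configuration for `convrf run --config examples/run.yaml`
design:
  n_train_ensembles: 4
  n_reg_ensembles: 2
  n_test_ensembles: 2
  frames_per_ensemble: 375
  repeats_train: 5
  repeats_reg: 20
  repeats_test: 20
  blank_leadin_frames: 8
training:
  learning_rate: 0.005
  patience: 60
  max_epochs: 600
  filter_sizes: [11]
  min_crop_px: 30
  input_size: 30
  n_lags: 7
  passes: 1
  batch_frames: 512
neuron:
  alpha_true: 0.0     # complex-like generator
  k: 11
  input_size: 30
  reliability: 0.3
  sf_cycles_per_px: 0.15
  orientation_deg: 40.0
seed: 3
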