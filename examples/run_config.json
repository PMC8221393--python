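{
  "out_dir": "cardiomorph_run",
  "dpf": 4,
  "pitch": 4.0,
  "frames": 20,
  "sim_seed": 0,
  "n_slices": 120,
  "slice_size": 128,
  "slice_seed": 0,
  "epochs": 30,
  "batch_size": 8,
  "learning_rate": 0.001,
  "train_fraction": 0.8,
  "train_seed": 0,
  "se_radius": 1,
  "max_iterations": 50,
  "identity_rule": "larger-is-ventricle"
}
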