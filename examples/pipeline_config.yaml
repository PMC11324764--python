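# Example pipeline config for `mazeskill run-all --config pipeline_config.yaml`
# Every constant named in the module documentation has a default; only
# overrides need to appear here.
seed: 1
output_dir: mazeskill_out
days: [1, 2, 3]
trials_per_day: 12
kin_seconds_per_day: 30.0
tactile_trials_per_day: 40
tactile_frames_per_trial: 6
learning_model:
  intercept: 0.57071
  slope: 0.0001016
  resid_sd: 0.13
penalties: {}            # e.g. {RollToCorner: 0.05}
segmentation: {}         # e.g. {v_rest: 5.0, T_rest: 0.5}
generator: {}            # e.g. {noise_sd_mm: 0.5}
plots: true
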