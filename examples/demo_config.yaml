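# Demo configuration for `rnpstoich run --config examples/demo_config.yaml --out out --seed 1`.
# Simulates a mostly-processive track population, classifies it, extracts
# kinetics, and infers the copy-number mixture from simulated dual-colour
# labelling of an obligate dimer at 90% labelling efficiency.
seed: 1
sim:
  n_tracks: 500
  class_probs: [0.1, 0.1, 0.8]
  run_length_mean: 5.0
  velocity_mean: 1.0
  localisation_sd: 0.05
labeling:
  mode: binomial_snap
  p_label: 0.9
  q_dyeA: 0.5
simulate_counts:
  n_complexes: 400
  two_copy_fraction: 1.0
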