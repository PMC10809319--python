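# Default desk-scale pipeline configuration: gated-pocket dynamic docking.
# Units: Å, kcal/mol, K.  All randomness derives from the --seed flag.
system:
  potential_id: gated_pocket

schedule:
  n_trajectories: 2
  prerun_steps: 40000
  production_steps: 120000
  bias_update_iterations: 5
  snapshot_stride: 60
  step_width: 0.35

reweight:
  temperature: 300.0

fel:
  grid: [60, 60]
  cfe_cutoff: 1.0

validate:
  T_list: [300.0, 400.0]
  n_replicas: 3
  length: 20000
  window: 0.4
  max_representatives: 2

path:
  windows: auto
  n_windows: 5
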