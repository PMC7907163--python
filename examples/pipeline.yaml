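# Smoke-scale end-to-end configuration (completes in ~1 minute).
seed: 5
cohort:
  n_per_group: 3
  n_roi: 16
  runs_per_condition: 1
  volumes_per_run: 64
  n_group_edges: 5
  n_condition_edges: 5
training:
  max_epochs: 6
  patience: 4
  k_folds: 2
decimation:
  n_families: 2
  stop_fraction: 0.5
transfer:
  n_per_group: 2
  runs_per_participant: 1
  n_sets: 1
  partitions_per_set: 1
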