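# Demo pipeline configuration: a small two-channel synthetic experiment.
# fast channel -> diffusive-state classification (pEM + BIC)
# slow channel + bound control -> photobleach-corrected residence times
seed: 1
out: runs/demo

protocols:
  fast: {frame_interval_s: 0.012, exposure_s: 0.010, n_frames: 21}
  slow: {frame_interval_s: 0.200, exposure_s: 0.010, n_frames: 200}

simulate:
  fast:
    n_tracks: 600
    states:
      - {label: bound, diffusivity_um2_s: 0.02}
      - {label: free, diffusivity_um2_s: 0.5}
    initial_weights: [0.3, 0.7]
    localization_sigma_um: 0.03
  slow:
    n_tracks: 1500
    localization_sigma_um: 0.03
    residence:                       # chromatin-bound molecules, power-law residence
      alpha: 2.0
      t_min_s: 0.2
      d_bound_um2_s: 0.005
      n_cells: 4
      bleach_amplitudes: [0.5, 0.3, 0.2]
      bleach_timescales_s: [0.5, 2.0, 10.0]
  control:
    n_tracks: 2000
    bleach_amplitudes: [0.5, 0.3, 0.2]
    bleach_timescales_s: [0.5, 2.0, 10.0]

states:
  k_min: 1
  k_max: 3
  n_restarts: 2
  n_perturbations: 2
  bound_D_max_um2_s: 0.03
  max_lag: 5

dwell:
  bound_radius_um: 0.2
  min_bound_frames: 2
  t_min_s: 0.6
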