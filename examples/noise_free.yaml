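# Packaged 4+4-subject noise-free fixture configuration.
# Run: motionlat run-all --config examples/noise_free.yaml --out-dir results/fixture
simulation:
  n_per_group:
    TC: 4
    WS: 4
  n_trials: 6
  sampling_rate: 250.0
  epoch_window:
  - -100.0
  - 1000.0
  group_means:
    TC: -1.5
    WS: 0.8
  sensitivity_scale: 0.8
  allocation_params:
    TC:
    - 0.33
    - 8.0
    WS:
    - 0.58
    - 9.0
  left_handed:
    TC: 0
    WS: 1
  n_female:
    TC: 2
    WS: 2
  component_params:
    P1:
      latency_ms: 155.0
      width_ms: 15.0
      amplitude_uV: 4.0
      electrode_role: occipital_set
      conditions:
      - M_SL
      - M_SR
      window_ms:
      - 130.0
      - 170.0
    N1:
      latency_ms: 148.0
      width_ms: 15.0
      amplitude_uV: -4.0
      electrode_role: occipital_set
      conditions:
      - P_CHANGE
      window_ms:
      - 130.0
      - 170.0
    N2:
      latency_ms: 190.0
      width_ms: 15.0
      amplitude_uV: -5.0
      electrode_role: hemisphere_sets
      conditions:
      - M_SL
      - M_SR
      window_ms:
      - 155.0
      - 195.0
  noise_sd: 0.0
  pink_fraction: 0.2
  eog_noise_scale: 0.3
  artifact_rate: 0.0
  artifact_amplitudes:
    blink: 300.0
    hem: 60.0
    spike: 250.0
  rho_expression: 0.465
  rho_methylation: -0.4
  expression_features:
    BUD23: null
    BCL7B: 0.3
    BAZ1B: 0.3
    HPRT1: 0.0
    ACTB: 0.0
  methylation_features:
    cg12099727: null
    cg09265173: 0.3
  expression_batch_scales:
    batch1:
    - 1.0
    - 0.2
    batch2:
    - 5.0
    - 1.0
  seed: 202
layout:
  occipital_set:
  - O1
  - I1
  - IZ
  - I2
  - O2
  lh_set:
  - P5
  - PO3
  - PO7
  rh_set:
  - P4
  - PO4
  - PO8
  mastoids:
  - M1
  - M2
  veog:
  - VEOG
  heog: HEOG
preprocess:
  lowpass_hz: 30.0
  filter_order: 4
  baseline_window:
  - -100.0
  - 0.0
  amp_threshold_uV: 200.0
  heog_threshold_uV: 40.0
  veog_threshold_uV: 100.0
  min_trials: 40
  order:
  - rereference
  - baseline
  - reject
  - average
  - lowpass
epsilon_uV: 0.0
z_reference: combined
adjust_method: bonferroni
plan:
- feature: BUD23
  phenotype: LI
  tail: one_pos
- feature: BUD23
  phenotype: S_R
  tail: one_neg
- feature: BUD23
  phenotype: S_L
  tail: one_pos
- feature: BCL7B
  phenotype: LI
  tail: two
- feature: BAZ1B
  phenotype: LI
  tail: two
- feature: HPRT1
  phenotype: LI
  tail: two
- feature: ACTB
  phenotype: LI
  tail: two
- feature: cg12099727
  phenotype: LI
  tail: one_neg
- feature: cg09265173
  phenotype: LI
  tail: two
seed: 202
log_level: INFO
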