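# Study-design defaults: 5 dystrophic + 6 wild-type littermates followed
# monthly from 2 to 12 months of age; four 15-m passes per session recorded
# at 20 ms with a 10 s standing window for gravity calibration.
name: study_defaults
seed: 0
dogs:
  - {id: 13103FN, phenotype: WT, sex: F}
  - {id: 13102MA, phenotype: DYS, sex: M}
  - {id: 13301MN, phenotype: WT, sex: M}
  - {id: 13303MA, phenotype: DYS, sex: M}
  - {id: 13401MA, phenotype: DYS, sex: M}
  - {id: 13402FN, phenotype: WT, sex: F}
  - {id: 13802MA, phenotype: DYS, sex: M}
  - {id: 13804MN, phenotype: WT, sex: M}
  - {id: 13805MN, phenotype: WT, sex: M}
  - {id: 14102MA, phenotype: DYS, sex: M}
  - {id: 14103MN, phenotype: WT, sex: M}
months: [2, 12]
regions: [thoracic, lumbar]
trial:
  duration_s: 14.0
  standing_s: 10.0
  sampling_interval_ms: 20.0
  passes_per_session: 4
gait:
  stride_frequency: {WT: 2.8, DYS: 2.2}
  wt_axis_amplitudes:
    thoracic: [2.0, 0.8, 1.2]
    lumbar: [1.8, 0.9, 1.4]
  wt_gyro_amplitudes:
    thoracic: [150.0, 300.0, 120.0]
    lumbar: [140.0, 160.0, 200.0]
  dys_factor_start: 0.6
  dys_factor_end: 0.25
  noise_sd: 0.05
  dog_factor_range_wt: [0.85, 1.15]
  dog_factor_range_dys: [0.6, 1.0]
outcomes:
  - name: AM
    transform: log
    sigma0_sq: 0.04
    sigma1_sq: 0.01
    anchors:
      WT:
        thoracic: {2: 1.2, 4: 2.0, 12: 1.5}
        lumbar: {2: 1.0, 7: 1.9, 12: 1.6}
      DYS:
        thoracic: {2: 0.55, 12: 0.25}
        lumbar: {2: 0.85, 12: 0.3}
    betas: {clinical_score: -0.3, locomotor_activity: 0.3}
covariates:
  kinds: [clinical_score, locomotor_activity]
  severity: 0.7
mri:
  group_shift: 30.0
  coupling: {TC: -1.0, EDL: -0.8, FDL: 0.3, FHL: 0.3, GM: -0.5, GL: 0.8, FDS: 0.8}
  coupling_scale: 8.0
  noise_sd: 2.0
  sd_air: 4.0
  n_rois_per_side: 3
mcmc: {chains: 2, iterations: 4000, burn_in: 2000, thin: 1, seed: 0}
apply_missing_pattern: true
write_trials: false
standardize_covariate: true
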