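# Planted-effect configuration: wide wild-type vs dystrophic trend
# separation for AM in both regions and strong covariate effects
# (beta = -0.8 on the standardized clinical score, +0.8 on standardized
# locomotor activity).  Trials are shorter (two passes, 10 s recordings)
# than the full design so end-to-end runs stay quick.
name: strong_effect
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
  duration_s: 10.0
  standing_s: 6.0
  sampling_interval_ms: 20.0
  passes_per_session: 2
gait:
  stride_frequency: {WT: 2.8, DYS: 2.2}
  wt_axis_amplitudes:
    thoracic: [2.0, 0.8, 1.2]
    lumbar: [1.8, 0.9, 1.4]
  wt_gyro_amplitudes:
    thoracic: [150.0, 300.0, 120.0]
    lumbar: [140.0, 160.0, 200.0]
  dys_factor_start: 0.5
  dys_factor_end: 0.2
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
        thoracic: {2: 1.4, 4: 2.2, 12: 1.8}
        lumbar: {2: 1.2, 7: 2.1, 12: 1.8}
      DYS:
        thoracic: {2: 0.45, 12: 0.18}
        lumbar: {2: 0.6, 12: 0.2}
    betas: {clinical_score: -0.8, locomotor_activity: 0.8}
covariates:
  kinds: [clinical_score, locomotor_activity]
  severity: 0.8
mri:
  group_shift: 35.0
  coupling: {TC: -1.0, EDL: -0.9, FDL: 0.3, FHL: 0.3, GM: -0.6, GL: 0.9, FDS: 0.9}
  coupling_scale: 10.0
  noise_sd: 1.0
  sd_air: 4.0
  n_rois_per_side: 3
mcmc: {chains: 2, iterations: 4000, burn_in: 2000, thin: 1, seed: 0}
apply_missing_pattern: true
write_trials: false
standardize_covariate: true
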