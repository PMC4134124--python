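# Demo: simulate a 50,000-person cohort over the 1991-2010 record span and
# run the full incidence pipeline for the 1996-2009 study years.
#
#   ibdclaims all --config examples/demo_config.yaml --out scratch/demo
#
simulation:
  seed: 20140809
  n_persons: 50000
  calendar_span: [1991, 2010]
  washout_span: [1991, 1995]
  sex_ratio: 0.51
  annual_trend: {CD: 0.97, UC: 0.978}
  claims_per_year_post_onset: 4.0
  hospitalization_prob_per_year: 0.15
  code_noise_prob: 0.10
  icd10_transition_year: 2001
  background_encounter_rate: 2.0

pipeline:
  study_span: [1996, 2009]
  washout_span: [1991, 1995]
  classification_window_days: 730
  gate: {min_hospitalizations: 1, min_claims: 4, window_days: 730}
  weights:
    claim_uc: 1
    claim_cd: -1
    discharge_uc: 2
    discharge_cd: -2
    uc_threshold: 2
    cd_threshold: -2
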