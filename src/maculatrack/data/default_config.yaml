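effects:
  control:
    early: 3.92
    mid: 3.08
    delivery: 5.16
  denovo_hdp:
    early: 4.35
    mid: 2.99
    delivery: 3.45
  chtn_lot:
    early: 3.39
    mid: 2.85
    delivery: 1.06
  chtn_nolot:
    early: 3.91
    mid: 3.8
    delivery: 4.46
map_plans:
  control:
    enroll_mean: 84.0
    enroll_sd: 4.0
    mid_step_mean: 2.0
    delivery_step_mean: 5.0
    step_sd: 3.0
    baseline_mean: 84.0
  denovo_hdp:
    enroll_mean: 84.0
    enroll_sd: 4.0
    mid_step_mean: -2.0
    delivery_step_mean: 19.0
    step_sd: 3.0
    baseline_mean: 85.0
  chtn_lot:
    enroll_mean: 87.0
    enroll_sd: 4.0
    mid_step_mean: 11.0
    delivery_step_mean: 4.0
    step_sd: 3.0
    baseline_mean: 92.0
  chtn_nolot:
    enroll_mean: 92.0
    enroll_sd: 4.0
    mid_step_mean: 5.0
    delivery_step_mean: 20.0
    step_sd: 3.0
    baseline_mean: 93.0
baseline_sectors:
  C: 250.0
  IS: 284.0
  IN: 286.0
  II: 283.0
  IT: 281.0
  OS: 269.0
  'ON': 272.0
  OI: 266.0
  OT: 262.0
late_early_change: 1.0
lot:
  n_sectors: 3
  early_extra: 3.0
  seq_jump: 6.0
  growth: 0.5
hypo:
  sudden_um: 6.0
  compensate: true
  map_drop_mean: 21.0
  map_drop_sd: 2.0
  map_drop_min: 16.0
noise:
  replicate_sd: 0.7215
  participant_sd: 0.6
  eye_sd: 0.35
  sector_sd: 0.35
  visit_sd: 0.5
  visit_corr_length: 20.0
  level_participant_sd: 12.0
  level_eye_sd: 2.5
  level_sector_sd: 1.5
composition:
  n_control: 11
  n_denovo: 12
  n_chtn_lot: 8
  n_chtn_nolot: 7
  single_eye_denovo: 4
  single_eye_chtn_lot: 3
  delivery_onset_chtn_lot: 3
  hypo_denovo: 2
  hypo_chtn_lot: 2
  hypo_chtn_nolot: 1
  n_late_early: 1
schedule:
  early_week: 12.0
  mid_week: 30.0
  delivery_week: 38.0
  crisis_lead: 2.0
  visit_jitter: 2.0
  baseline_weeks_postpartum: 31.0
plant_spatial: true
signal_strength_range:
- 7.0
- 10.0
pulse_pressure_mean: 42.0
pulse_pressure_sd: 5.0
seed: 20210617
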