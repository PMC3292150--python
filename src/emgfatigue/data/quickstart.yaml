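# Small end-to-end demonstration configuration (3 subjects x 2 trials, 120 s).
# Constants of record: angle boundaries 86.5/89 deg, oscillation crossover
# 0.6 deg SD, band-pass 1-500 Hz order 5, 1-s feature windows, 3-s rolling SD,
# 4-s oscillation blocks, moment band 8-500 Hz, db3 wavelet at level 12.
simulate:
  n_subjects: 3
  trials_per_subject: 2
  jitter: 0.1
  base:
    duration_s: 120
    t_tf: 70
    t_f: 100
    mdf_start: 95.0
    mdf_end: 55.0
    amp_gain: 1.6
    angle_hold: 90.0
    angle_end: 84.0
    osc_sd_nf: 0.2
    osc_sd_tf: 1.0
    noise_sd: 0.05
    seed: 0
filter:
  low_hz: 1.0
  high_hz: 500.0
  order: 5
fuzzy:
  angle:
    NF: [86.5, 89.0, 180.0, 180.0]
    TF: [86.5, 87.75, 89.0]
    F: [0.0, 0.0, 86.5, 89.0]
  osc:
    Low: [0.0, 0.0, 0.4, 0.8]
    High: [0.4, 0.8, 10.0, 10.0]
  osc_window_s: 4.0
features:
  channel: 1
  span_s: 3
  fi_moments: [2]
  wavelet: db3
  level: 12
classify:
  train_frac: 0.5
report:
  reference_feature: spectro_std
  dbi_spans: [1, 2, 3, 4, 5]
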