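# Study-calibrated cohort specification.
#
# Per-cell means (keys "tooth/trial") encode the printed group means of the
# four experience groups: distance between centers (mm), relative area ratio
# of the lesion image on the mirror (%), ellipticity of the lesion image
# (per trial) and manipulation time (s).  Cells whose group mean was not
# printed (only significant contrasts were reported per tooth) are filled
# with order-consistent interpolations and marked "# est".
#
# Group sizes: 25 instructor dentists (ID), 24 graduate students (GS),
# 17 trainee dentists (TD), 21 sixth-year students (ST).
#
# Dispersion parameters (offset_shape, ratio_sd_pct, ellipticity_sd,
# time_sigma_log) are generator choices, not reported quantities: Gamma shape
# 4 gives a coefficient of variation of 0.5 for radial offsets, consistent
# with the reported between-group effect sizes (|d| ~ 0.5 for ~0.4 mm mean
# differences implies a pooled SD near 0.8 mm across tasks).

seed: 0
trials: [1, 2]
capture_vfov_deg: 16.0
capture_px: 800
viewer_distance_mm: 300.0

groups:
  ID:
    n: 25
    offset_mean_mm: 1.15
    offset_shape: 4.0
    offset_mean_by_cell:
      "12/1": 1.33
      "21/1": 1.18
      "31/1": 0.87
      "42/1": 1.06
      "12/2": 1.30
      "21/2": 1.18   # est
      "31/2": 1.23
      "42/2": 1.04
    ratio_target_mean_pct: 2.95
    ratio_sd_pct: 0.35
    ratio_mean_by_cell:
      "12/1": 3.46
      "21/1": 2.85
      "31/1": 2.96
      "42/1": 2.77
      "12/2": 3.28
      "21/2": 2.78
      "31/2": 3.03
      "42/2": 2.66
    ellipticity_target_mean: 0.89
    ellipticity_sd: 0.05
    ellipticity_mean_by_trial: {"1": 0.89, "2": 0.89}
    time_mean_s: 6.6
    time_sigma_log: 0.35
    time_mean_by_cell:
      "12/1": 7.4
      "21/1": 8.3
      "31/1": 6.3
      "42/1": 6.1
      "12/2": 6.5   # est
      "21/2": 7.4
      "31/2": 5.3
      "42/2": 5.8
    task_time_factors: {"1": 1.3}
  GS:
    n: 24
    offset_mean_mm: 1.47
    offset_shape: 4.0
    offset_mean_by_cell:
      "12/1": 1.62
      "21/1": 1.59
      "31/1": 1.03
      "42/1": 1.47
      "12/2": 1.64
      "21/2": 1.59   # est
      "31/2": 1.12
      "42/2": 1.71
    ratio_target_mean_pct: 2.85
    ratio_sd_pct: 0.35
    ratio_mean_by_cell:
      "12/1": 3.32
      "21/1": 2.74
      "31/1": 2.87
      "42/1": 2.65
      "12/2": 3.30   # est
      "21/2": 2.70   # est
      "31/2": 2.79
      "42/2": 2.66
    ellipticity_target_mean: 0.88
    ellipticity_sd: 0.05
    ellipticity_mean_by_trial: {"1": 0.88, "2": 0.88}   # est
    time_mean_s: 9.0
    time_sigma_log: 0.35
    time_mean_by_cell:
      "12/1": 11.3
      "21/1": 11.0
      "31/1": 8.1
      "42/1": 7.7
      "12/2": 8.1
      "21/2": 8.0   # est
      "31/2": 7.3
      "42/2": 9.6
    task_time_factors: {"1": 1.3}
  TD:
    n: 17
    offset_mean_mm: 1.54
    offset_shape: 4.0
    offset_mean_by_cell:
      "12/1": 1.55   # est
      "21/1": 1.50   # est
      "31/1": 1.07
      "42/1": 1.43
      "12/2": 2.04
      "21/2": 1.73   # est
      "31/2": 1.37   # est
      "42/2": 1.81
    ratio_target_mean_pct: 2.60
    ratio_sd_pct: 0.35
    ratio_mean_by_cell:
      "12/1": 2.93
      "21/1": 2.56
      "31/1": 2.59
      "42/1": 2.35
      "12/2": 3.07
      "21/2": 2.51
      "31/2": 2.61
      "42/2": 2.32
    ellipticity_target_mean: 0.86
    ellipticity_sd: 0.05
    ellipticity_mean_by_trial: {"1": 0.86, "2": 0.86}
    time_mean_s: 6.6
    time_sigma_log: 0.35
    time_mean_by_cell:
      "12/1": 8.1
      "21/1": 8.4
      "31/1": 6.1
      "42/1": 5.5
      "12/2": 5.8
      "21/2": 8.3
      "31/2": 4.7
      "42/2": 6.7
    task_time_factors: {"1": 1.3}
  ST:
    n: 21
    offset_mean_mm: 1.65
    offset_shape: 4.0
    offset_mean_by_cell:
      "12/1": 1.77
      "21/1": 1.56
      "31/1": 1.69
      "42/1": 1.64
      "12/2": 1.70
      "21/2": 1.60   # est
      "31/2": 1.59
      "42/2": 1.66
    ratio_target_mean_pct: 2.80
    ratio_sd_pct: 0.35
    ratio_mean_by_cell:
      "12/1": 3.23
      "21/1": 2.52
      "31/1": 2.81
      "42/1": 2.50   # est
      "12/2": 3.38
      "21/2": 2.60   # est
      "31/2": 2.84
      "42/2": 2.51
    ellipticity_target_mean: 0.87
    ellipticity_sd: 0.05
    ellipticity_mean_by_trial: {"1": 0.87, "2": 0.87}   # est
    time_mean_s: 7.0
    time_sigma_log: 0.35
    time_mean_by_cell:
      "12/1": 7.9
      "21/1": 8.5
      "31/1": 6.1
      "42/1": 6.0   # est
      "12/2": 7.0   # est
      "21/2": 7.5   # est
      "31/2": 6.0   # est
      "42/2": 6.5   # est
    task_time_factors: {"1": 1.3}
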