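# Default study conditions: per-group modulus distributions (median/IQR,
# kPa), collagen densities (%) and sample sizes of the healthy vs
# atherosclerotic coronary cohort, with 5% relative force noise.
seed: 0
groups:
  - {label: healthy_wall, median_E_kPa: 11.0, iqr_E_kPa: 8.6, n_rois: 67,
     n_curves: 1379, median_density_pct: 32.4, n_density_rois: 67}
  - {label: lipid_core, median_E_kPa: 2.2, iqr_E_kPa: 1.7, n_rois: 16,
     n_curves: 392, median_density_pct: 2.7, n_density_rois: 7}
  - {label: fibrous_cap_shoulder, median_E_kPa: 4.8, iqr_E_kPa: 3.4, n_rois: 26,
     n_curves: 638, median_density_pct: 17.8, n_density_rois: 14}
  - {label: fibrous_cap_mid, median_E_kPa: 5.1, iqr_E_kPa: 2.8, n_rois: 35,
     n_curves: 868, median_density_pct: 14.7, n_density_rois: 10}
noise:
  relative_force_noise: 0.05
  baseline_offset_nN: 0.2
  baseline_slope_nN_per_um: 0.05
  contact_jitter_sd_um: 0.05
tip: {half_angle_deg: 20.0, poisson_ratio: 0.5}
spring_constant_N_per_m: 0.6
section_thickness_um: 20.0
threshold: 75
bin_size: 6
density_rho: 0.6
comparisons:
  - [healthy_wall, plaque]
  - [lipid_core, fibrous_cap]
  - [fibrous_cap_shoulder, fibrous_cap_mid]
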