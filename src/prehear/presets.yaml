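# Calibrated generator presets, one block per modality and genotype.
# Calibration: constants were fixed once by simulating cohorts at the study
# sizes and matching the analysis pipeline's group statistics to the target
# phenotypes; see docs/methods.md.
version: 1

spikes:
  wt:
    label: WT
    duration: 100.0
    burst_rate_per_100s: 5.5
    miniburst_count_median: 15.0
    miniburst_count_sigma: 1.05
    miniburst_count_min: 8
    miniburst_interval: 0.1
    miniburst_interval_sd: 0.015
    spikes_per_miniburst_extra: 1.5
    spikes_per_miniburst_sigma: 0.55
    intra_miniburst_isi: 0.025
    intra_isi_sd: 0.006
    background_rate: 0.6
    unit_jitter_sd: 0.4
  cko:
    label: cKO
    duration: 100.0
    burst_rate_per_100s: 4.5
    miniburst_count_median: 7.0
    miniburst_count_sigma: 0.7
    miniburst_count_min: 2
    miniburst_interval: 0.1
    miniburst_interval_sd: 0.015
    spikes_per_miniburst_extra: 1.5
    spikes_per_miniburst_sigma: 0.45
    intra_miniburst_isi: 0.025
    intra_isi_sd: 0.006
    background_rate: 1.0
    unit_jitter_sd: 0.4

imaging:
  wt_ca:
    label: WT
    modality: fura_ratio
    shape: [128, 128]
    pixel_size: 2.0
    n_frames: 400
    frame_interval: 1.0
    baseline_level: 2000.0
    noise_sd: 0.012
    event_rate: 0.08
    event_amplitude: 0.35
    area_median: 3250.0
    area_sigma: 0.45
    area_max: 15000.0
    rise_frames: 6
    hold_frames: 2
    decay_frames: 6
    propagation_speed: 3.0
    band_rows_um: [100.0, 156.0]
    x_margin_um: 40.0
  cko_ca:
    label: cKO
    modality: fura_ratio
    shape: [128, 128]
    pixel_size: 2.0
    n_frames: 400
    frame_interval: 1.0
    baseline_level: 2000.0
    noise_sd: 0.012
    event_rate: 0.017
    event_amplitude: 0.30
    area_median: 640.0
    area_sigma: 0.45
    area_max: 2500.0
    rise_frames: 6
    hold_frames: 2
    decay_frames: 6
    propagation_speed: 0.0
    band_rows_um: [100.0, 156.0]
    x_margin_um: 40.0
  wt_dic:
    label: WT
    modality: dic
    shape: [128, 128]
    pixel_size: 2.0
    n_frames: 1200
    frame_interval: 1.0
    baseline_level: 2000.0
    noise_sd: 0.012
    event_rate: 0.040
    event_amplitude: 0.35
    area_median: 6500.0
    area_sigma: 0.40
    area_max: 15000.0
    rise_frames: 6
    hold_frames: 2
    decay_frames: 6
    propagation_speed: 3.0
    band_rows_um: [100.0, 156.0]
    x_margin_um: 40.0
  cko_dic:
    label: cKO
    modality: dic
    shape: [128, 128]
    pixel_size: 2.0
    n_frames: 1200
    frame_interval: 1.0
    baseline_level: 2000.0
    noise_sd: 0.012
    event_rate: 0.0006
    event_amplitude: 0.25
    area_median: 60.0
    area_sigma: 0.40
    area_max: 300.0
    rise_frames: 6
    hold_frames: 2
    decay_frames: 6
    propagation_speed: 0.0
    band_rows_um: [100.0, 156.0]
    x_margin_um: 40.0

fra:
  wt:
    cf_khz: 15.0
    threshold_db: 10.0
    slope_low: 70.0
    slope_high: 90.0
    max_rate: 260.0
    spont_rate: 5.0
    dynamic_range_db: 15.0
    reps: 20
    window_s: 0.1
  cko:
    cf_khz: 16.0
    threshold_db: 16.0
    slope_low: 40.0
    slope_high: 55.0
    max_rate: 220.0
    spont_rate: 5.0
    dynamic_range_db: 15.0
    reps: 20
    window_s: 0.1

map:
  wt:
    label: WT
    grid_spacing: 20.0
    mntb_area_um2: 63000.0
    mntb_aspect: 1.4
    area_jitter_sd: 0.07
    frac_area_target: 0.10
    width_frac_target: 0.18
    width_pad_um: 25.0
    peak_mv: 30.0
    ap_threshold_mv: 22.0
    noise_sd_mv: 0.5
    n_polygon_vertices: 48
  cko:
    label: cKO
    grid_spacing: 20.0
    mntb_area_um2: 55000.0
    mntb_aspect: 1.4
    area_jitter_sd: 0.07
    frac_area_target: 0.20
    width_frac_target: 0.36
    width_pad_um: 25.0
    peak_mv: 32.0
    ap_threshold_mv: 22.0
    noise_sd_mv: 0.5
    n_polygon_vertices: 48
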