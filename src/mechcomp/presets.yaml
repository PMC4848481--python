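# Fixture parameter presets for the synthetic-data generator.
#
# These encode the study conditions the pipeline is validated against:
# a wild-type MDCK homeostatic plateau of 61 cells per 10,000 um^2 on
# 800-um circular micropatterns, a loser (scrib-KD-like) confluent density
# of ~1/3 of that, a surrounded loser clone compacted 4.5-fold above pure
# loser cultures, a 3-fold compression apoptosis increase, a ~2 h
# winner-before-loser migration-onset lag, a density-marker Spearman rank
# correlation of 0.56 in competing conditions, and Nutlin-3-treated MTEC
# endpoints (26% monoculture density reduction; loser count down to 17%
# of baseline by day 6 of competition).

wt_homeostasis:
  geometry: {shape: disc, diameter: 800.0, pixel_size: 0.65, frame_interval: 2.0}
  target_density: 61.0          # cells per 10,000 um^2
  min_spacing: 5.0              # um, hard-core exclusion between nuclei
  growth_rate: 0.08             # logistic rate, 1/h
  seed_fraction: 0.30           # initial count as fraction of carrying count
  duration_h: 144.0
  noise_cv: 0.02

pure_loser:
  geometry: {shape: rectangle, width: 500.0, height: 500.0, pixel_size: 0.65, frame_interval: 2.0}
  target_density: 20.3333       # ~1/3 of the wild-type plateau
  min_spacing: 5.0

pure_winner:
  geometry: {shape: rectangle, width: 500.0, height: 500.0, pixel_size: 0.65, frame_interval: 2.0}
  target_density: 61.0
  min_spacing: 5.0

competition_scene:
  geometry: {shape: rectangle, width: 500.0, height: 500.0, pixel_size: 0.65, frame_interval: 2.0}
  clone_radius: 100.0           # um, surrounded loser clone
  loser_pure_density: 20.3333
  density_ratio_clone_vs_pure: 4.5
  winner_density: 61.0
  min_spacing: 4.0
  clone_gap: 4.0                # um free annulus between clone and winners

copula_competing:
  marker_rank_corr: 0.56        # competing-condition density/marker association
  sigma_um: 20.0
  radius_um: 50.0
  lognormal_sigma: 0.4
  lognormal_median: 100.0

contact_migration:
  geometry: {shape: rectangle, width: 400.0, height: 300.0, pixel_size: 0.65, frame_interval: 0.25}
  n_per_population: 80
  duration_h: 12.0
  t_contact_h: 3.0              # winner migration onset
  onset_lag_h: 2.0              # loser onset = t_contact + lag
  pre_contact_speed: 4.0        # um/h
  post_contact_speed: 12.0
  pre_persistence: 0.5
  post_persistence: 0.9
  directed_fraction: 1.0
  min_spacing: 12.0
  gap_um: 30.0                  # initial free corridor between populations

compression_assay:
  n_cells: 20000
  exposure_h: 1.0               # single fixed-endpoint interval, as in a
                                # stain-after-release compression assay
  baseline_death_rate: 0.05     # events per cell per h, uncompressed
  compression_death_multiplier: 3.0
  geometry: {shape: rectangle, width: 6600.0, height: 13000.0, pixel_size: 0.65, frame_interval: 1.0}

treatment_monoculture:
  baseline_count: 2000
  t_event_h: 72.0               # treatment (e.g. Nutlin-3) addition
  duration_h: 240.0
  frame_interval_h: 4.0
  endpoint_fraction: 0.74       # 26% density reduction
  decay_tau_h: 24.0
  noise_cv: 0.02
  area_um2: 1.0e6

treatment_competition:
  baseline_count: 2000          # loser (wild-type-labelled) population
  other_count: 4000             # unlabelled partner population
  t_event_h: 72.0
  duration_h: 240.0
  frame_interval_h: 4.0
  day6_fraction: 0.17           # loser count at event + 144 h
  noise_cv: 0.02
  area_um2: 1.0e6

loser_collapse:
  baseline_count: 1500
  growth_rate: 0.06
  peak_time_h: 48.0
  collapse_fraction: 0.40       # final count as fraction of peak
  duration_h: 144.0
  frame_interval_h: 4.0
  noise_cv: 0.02
  area_um2: 5.02655e5
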