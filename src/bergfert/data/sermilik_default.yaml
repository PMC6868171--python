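# Default configuration: summertime Sermilik-fjord-like conditions.
# Every block maps onto a config dataclass; unknown keys are rejected.

geometry_rules:
  aspect: 0.62            # width = aspect * length
  keel_c1: 2.91           # keel = keel_c1 * length**keel_c2 (m)
  keel_c2: 0.71
  max_keel: 600.0         # m
  density_ratio: 0.895    # draft fraction of total height

forcing:
  tw_surface: 3.0         # deg C at the waterline
  tw_bottom: 1.0          # deg C at/below tw_bottom_depth
  tw_bottom_depth: 300.0  # m
  freezing_temp: -1.8     # deg C
  u_rel: 0.06             # iceberg-ocean relative speed, m/s
  sea_state: 1.5
  sea_ice: 0.0            # concentration in [0, 1]
  air_temp: 0.0           # deg C
  sw_flux: 200.0          # W/m^2
  wave_amplitude: 1.0     # m

scenario:
  scenario: monte_carlo   # shell | basal | monte_carlo
  high_fe: 1.0e-4         # mol/L (100 uM sediment-rich ice)
  low_fe: 1.7e-7          # mol/L (170 nM background ice)
  high_fraction: 0.09     # volume fraction of high-Fe ice
  albedo_clean: 0.7
  albedo_dirty: 0.3
  seed: 0

sim:
  start_day_of_year: 121  # May 1
  duration_days: 180
  dt_days: 1.0
  wave_mode: full_face    # waterline | full_face
  instability_threshold: 0.92

population:
  length_range: [50.0, 1000.0]
  interval: 50.0
  exponent: 2.0

generator:
  weight_high: 0.09
  log_mean_low: -15.76824186
  log_sd_low: 1.65001726
  log_mean_high: -12.10368262
  log_sd_high: 2.76194822
  clip: [2.1e-9, 1.9e-3]

fertilization:
  melt_fraction: 0.001
  mld: 100.0
  duration_days: 30.0
  recycling: 2.0          # 1/fe ratio
  fe_to_c: 3.0            # umol Fe per mol C
  utilization: 1.0
  cap_mode: pp_cap
  pp_cap: 3000.0          # mg C m^-2 d^-1
  fe_cap: 2.0e-9          # mol/L post-mixing
  efficiency_mode: empirical
  constant_efficiency: 0.1
  ligand: 1.2e-9          # mol/L
  carbon_molar_mass: 12.011
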