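# Reference (calibrated) parameter set and run defaults.
#
# These values define the reference study conditions: an untreated
# doubling time of about 12 days, a three-phase response with resistance
# onset roughly four months into continuous BRAF/MEKi dosing, immediate
# resistance under the milder HCT, and strictly ordered resistance times
# across the four treatment scenarios.  Time unit: days; both domains are
# unit squares and all other quantities are dimensionless.

grid:
  n_spatial: 24
  n_structural: 24
  spatial_extent: 1.0
  structural_extent: 1.0

atlas:
  radius: 0.15
  anchors:
    proliferative: {position: [0.20, 0.20], cardinal: SW}
    invasive:      {position: [0.85, 0.50], cardinal: E}
    pigmented:     {position: [0.20, 0.85], cardinal: NW}
    NCSC:          {position: [0.85, 0.85], cardinal: NE}
    SMC:           {position: [0.50, 0.90], cardinal: N}
    URC:           {position: [0.80, 0.15], cardinal: SE}

structural_fluxes:
  k_adv: 1.5e-3       # 1/day, relaxation onto the proliferative--SMC attractor line
  d_h_min: 1.0e-5     # structural-length^2/day
  d_h_max: 5.0e-4
  d_v_min: 1.0e-5
  d_v_max: 7.0e-4

spatial_fluxes:
  D_x: 5.0e-5         # space^2/day
  chi_n: 5.0e-4       # chemotactic sensitivity (nutrient)
  chi_v: 5.0e-4       # haptotactic sensitivity (ECNE)
  rho_max: 100.0      # crowding capacity, cells/space^2
  volume_filling: diffusion

environment:
  r_v: 0.2
  v_max: 1.0
  lam_av: 0.1
  lam_v: 0.01
  D_n: 1.0e-3
  D_a: 1.0e-3
  D_w: 2.0e-3
  alpha_n: 0.9
  beta_n: 0.02
  lam_n: 0.4
  alpha_a: 0.01
  lam_a: 0.5
  lam_w: 0.5
  eps_w: 0.1          # cell-mediated drug uptake: dense tumors shield themselves

drug_response:
  BRAF_MEKi:
    components:
      - {center: proliferative, weight: 1.0, width: 0.18}
      - {center: invasive, weight: 0.5, width: 0.10}
    width: 0.18
    attenuation: {center: pigmented, width: 0.15, depth: 0.5}
    delta: 1.0
  HCT:
    components:
      - {center: invasive, weight: 1.0}
      - {center: URC, weight: 1.0}
    width: 0.25
    attenuation: null
    delta: 1.0

source:
  p_max: 0.12
  sigma_P: 0.75
  smc_suppression: 0.9
  sigma_S: 0.5
  n_half: 0.35

treatment:
  mode: continuous          # none | continuous | sequential | adaptive
  drug_order: [BRAF_MEKi]
  dose_rate: {BRAF_MEKi: 0.7, HCT: 0.8}
  switch_time: 110.0        # sequential mode: day of the drug swap
  decision_interval: 1.0    # adaptive mode: days between on/off decisions
  lower_threshold: 0.3      # fractions of the burden at treatment start
  upper_threshold: 0.5
  start_time: 50.0          # days of untreated growth before dosing begins

initial_condition:
  mass: 1.0
  spatial_center: [0.5, 0.5]
  structural_center: null   # default: the proliferative anchor
  spatial_sigma: 0.1
  structural_sigma: 0.1
  ecne_dip: 0.5

run:
  horizon: 300.0
  safety: 0.8
  max_dt: 0.25
  min_dt: 1.0e-5
  snapshot_interval: 5.0

metrics:
  smooth_width: 2.0
  mode_rel_threshold: 0.05
  slope_tol: 0.002
  min_phase_duration: 10.0
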