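# Single source of package defaults. Values are conventions of the CLM-family
# canopy models unless noted; everything here is overridable through
# sunshade.config.load_config(path) with a user YAML of the same shape.

kinetics:
  fnr: 7.16              # g Rubisco per g N in Rubisco
  sites_per_gram: 14.545 # umol catalytic sites per g Rubisco (8 sites / 550 kDa)
  jmax_ratio: 1.67       # Jmax25 / Vcmax25
  rd_ratio_c3: 0.015     # Rd25 / Vcmax25, C3 hosts
  rd_ratio_c4: 0.025     # Rd25 / Vcmax25, C4 hosts
  kp_ratio: 20000.0      # Kp25 / Vcmax25, C4 hosts
  ha_jmax: 43540.0       # J mol-1, shared across all C3 hosts
  hd: 149250.0           # J mol-1, C3 peaked deactivation
  delta_s: 485.0         # J mol-1 K-1, C3 peaked deactivation
  q10: 2.0               # C4 base temperature response
  s1: 0.3                # K-1, C4 high-temperature inhibition slope
  s2: 313.15             # K,   C4 high-temperature inhibition midpoint
  s3: 0.2                # K-1, C4 low-temperature inhibition slope
  s4: 288.15             # K,   C4 low-temperature inhibition midpoint
  o2: 209000.0           # umol mol-1 ambient O2
  sol_co2: 0.0334        # mol L-1 bar-1, CO2 solubility at 25 C
  sol_o2: 0.00126        # mol L-1 bar-1, O2 solubility at 25 C

radiation:
  vis_fraction: 0.5      # visible fraction of incoming shortwave
  beam_fraction: 0.7     # direct fraction of visible when not measured
  par_per_watt: 4.6      # umol photons per J (visible)
  sw_night_threshold: 5.0 # W m-2, below this a record counts as night

energy:
  cdry: 1.4              # J g-1 K-1, dry matter heat capacity
  cwat: 4.18             # J g-1 K-1, water heat capacity
  water_mass_fraction: 0.7

leafphys:
  phi_psii: 0.85         # quantum yield of PSII
  theta_psii: 0.7        # curvature of the light response
  alpha_c4: 0.05         # C4 quantum efficiency (mol CO2 / mol photons)
  theta1_c3: 0.98        # Ac/Aj smoothing, C3
  theta2_c3: 0.95        # (Ai)/Ap smoothing, C3
  theta1_c4: 0.80        # Ac/Aj smoothing, C4
  theta2_c4: 0.95        # (Ai)/Ap smoothing, C4

coupling:
  g0: 0.01               # mol m-2 s-1, minimum stomatal conductance
  g1_c3: 9.0             # Ball-Berry slope, C3
  g1_c4: 4.0             # Ball-Berry slope, C4
  tolerance: 0.001       # umol mol-1, Ci convergence criterion
  max_iter: 100
  ci0_frac_c3: 0.7       # initial Ci/Ca guess, C3
  ci0_frac_c4: 0.4       # initial Ci/Ca guess, C4
  dleaf: 0.04            # m, characteristic leaf dimension
  cv: 0.01               # m s-1/2, boundary-layer transfer coefficient
  u_min: 0.1             # m s-1, wind floor
  beta_soil: 1.0         # soil-moisture stress scalar on g1 (1 = off)

canopy:
  kn: 0.3                # nitrogen extinction coefficient, all crops

crops:
  wheat:
    native_species: Triticum aestivum
    pathway: C3
    latitude: 42.377
    lai_max: 2.27
    sla: 0.05            # m2 (g C)-1
    cn_ratio: 25.0       # g C (g N)-1
    flnr: 0.16
    xl: -0.3
    rho_leaf: 0.11
    tau_leaf: 0.05
    albedo_soil: 0.1
    dleaf: 0.04
  maize:
    native_species: Zea mays
    pathway: C4
    latitude: 40.006
    lai_max: 4.21
    sla: 0.08
    cn_ratio: 25.0
    flnr: 0.16
    xl: -0.3
    rho_leaf: 0.11
    tau_leaf: 0.05
    albedo_soil: 0.1
    dleaf: 0.06
  sugar_beet:
    native_species: Beta vulgaris
    pathway: C3
    latitude: 50.552
    lai_max: 4.0
    sla: 0.05
    cn_ratio: 25.0
    flnr: 0.16
    xl: 0.3
    rho_leaf: 0.11
    tau_leaf: 0.05
    albedo_soil: 0.1
    dleaf: 0.08
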