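# Organic matter turnover settings for the Luancheng silty loam fields.
# Pool kinetics under `defaults:` follow the conventional Daisy-style pool
# network (slow/fast SOM and SMB, slow/fast added organic matter, inert
# SOM3); they are package defaults, overridable per run.
water_factor: [[0.89, 0.01], [0.98, 0.01], [1.00, 0.01]]  # (rel. saturation, factor)
MaxRootingDepth: 190.0        # cm, end of root zone
smb_C_per_N: 4.8
annual_C_input_total:         # kg C / ha / y, warm-up background input
  A: 1550.0
  B: 800.0
annual_C_input_root:          # kg C / ha / y, root share of the above
  A: 750.0
  B: 600.0
nonroot_input_depth: 25.0     # cm, incorporation depth of non-root input
defaults:
  pool_rate_coefficients:     # 1/h first-order decay
    SOM1: 1.125e-7            # = 2.7e-6 per day
    SOM2: 5.83e-6             # = 1.4e-4 per day
    SMB1: 7.71e-6             # = 1.85e-4 per day
    SMB2: 4.17e-4             # = 1.0e-2 per day
    AOM1: 5.0e-4              # = 1.2e-2 per day
    AOM2: 2.08e-3             # = 5.0e-2 per day
  maintenance_rates:          # 1/h biomass maintenance (C to CO2, N to NH4)
    SMB1: 7.5e-5              # = 1.8e-3 per day
    SMB2: 4.17e-4             # = 1.0e-2 per day
  substrate_efficiencies:     # C incorporated per C decayed
    SOM1: 0.40
    SOM2: 0.50
    SMB1: 0.60
    SMB2: 0.60
    AOM1: 0.13
    AOM2: 0.69
  partition_fractions:        # receiver shares of each donor flow
    SOM1: {SMB1: 1.0}
    SOM2: {SOM1: 0.1, SMB1: 0.9}
    SMB1: {SOM2: 0.4, SMB2: 0.6}
    SMB2: {SOM2: 1.0}
    AOM1: {SMB1: 1.0}
    AOM2: {SMB2: 1.0}
  smb_init_fraction: 0.02     # SMB C as fraction of total soil C
  smb_init_split: [0.7, 0.3]  # SMB1 / SMB2
  humus_carbon_fraction: 0.587
  clay_factor_slope: 1.0      # f_clay = max(1 - slope*clay, clay_factor_min)
  clay_factor_min: 0.25
  turnover_t_ref: 10.0        # deg C at which f_T = 1
  turnover_q10: 2.0
  moisture_factor_knots: [[0.0, 0.0], [0.2, 0.2], [0.6, 1.0], [0.8, 1.0], [1.0, 0.5]]
  nitrification_rate: 0.1     # 1/d
  denitrification_rate: 0.1   # 1/d potential
  n2o_fraction_of_nitrification: 0.02
  dispersivity: 5.0           # cm
  molecular_diffusion: 0.05   # cm2/d effective in solution
  nh4_retardation: 3.0        # linear sorption retardation factor
  bulk_density: 1.4           # g/cm3
provenance:
  water_factor: calibrated
  MaxRootingDepth: measured
  smb_C_per_N: literature
  annual_C_input_total: calibrated
  annual_C_input_root: calibrated
  nonroot_input_depth: calibrated
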