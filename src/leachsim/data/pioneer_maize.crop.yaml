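# "Pioneer maize" parameterisation calibrated for the North China Plain.
# Values under `defaults:` are package defaults (not part of the calibrated
# field set) and may be overridden freely.
name: pioneer_maize
EmrTSum: 200.0        # soil degree-days to emergence
DSRate1: 0.0265       # 1/d, emergence -> flowering
Fm: 7.4               # g CO2 / m2 / h, light-saturated leaf photosynthesis
QEff: 0.045           # (g CO2 m-2 h-1) / (W m-2)
SpLAI: 0.02           # (m2/m2) per (g DM/m2)
E_Leaf: 0.68
E_Stem: 0.60
E_SOrg: 0.75
r_Leaf: 0.015         # 1/d maintenance respiration coefficients
r_Stem: 0.015
r_SOrg: 0.005
MaxPen: 150.0         # cm, maximum root penetration
MxNH4Up: 1.5e-7       # g N per cm root per hour
MxNO3Up: 1.5e-7
SpRtLength: 130.0     # m root per g root DM
C_per_N_slow_residue: 60.0
pet_factor_by_DS: [[0.0, 1.0], [1.0, 1.3], [2.0, 1.2]]
LeafAIMod_by_DS: [[0.0, 0.7], [0.5, 0.8], [1.0, 1.2], [2.0, 0.2]]
defaults:
  DSRate2: 0.030                      # 1/d, flowering -> maturity
  dev_temp_base: 8.0                  # deg C, development threshold
  dev_temp_plateau: 28.0              # deg C, f_T reaches 1
  photo_temp_knots: [[8.0, 0.0], [16.0, 1.0], [38.0, 1.0], [45.0, 0.0]]
  photo_ds_knots: [[0.0, 1.0], [1.0, 1.0], [2.0, 0.6]]
  extinction_coefficient: 0.6
  q10_maintenance: 2.0
  maintenance_t_ref: 20.0
  root_penetration_rate: 1.8          # cm/d at f_T = 1
  root_depth_fraction: 0.95           # root length above rooting depth
  aom_partition_slow: 0.5             # residue C fraction to the slow pool
  dm_carbon_fraction: 0.45            # g C per g DM
  partitioning_by_DS:                 # DS, root, leaf, stem, storage organ
    - [0.0, 0.40, 0.40, 0.20, 0.00]
    - [0.5, 0.25, 0.45, 0.30, 0.00]
    - [1.0, 0.10, 0.15, 0.35, 0.40]
    - [1.3, 0.05, 0.00, 0.10, 0.85]
    - [2.0, 0.00, 0.00, 0.00, 1.00]
  n_conc_by_DS:                       # target g N per g DM
    leaf: [[0.0, 0.045], [1.0, 0.035], [2.0, 0.015]]
    stem: [[0.0, 0.030], [1.0, 0.015], [2.0, 0.006]]
    sorg: [[0.0, 0.018], [2.0, 0.014]]
    root: [[0.0, 0.015], [2.0, 0.008]]
provenance:
  EmrTSum: measured
  DSRate1: calibrated
  Fm: calibrated
  QEff: calibrated
  SpLAI: measured
  E_Leaf: calibrated
  E_Stem: calibrated
  E_SOrg: calibrated
  r_Leaf: calibrated
  r_Stem: calibrated
  r_SOrg: calibrated
  MaxPen: measured
  MxNH4Up: calibrated
  MxNO3Up: calibrated
  SpRtLength: measured
  C_per_N_slow_residue: calibrated
  pet_factor_by_DS: literature
  LeafAIMod_by_DS: calibrated
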