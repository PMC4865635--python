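# Winter wheat parameterisation calibrated for the North China Plain.
# The development modifier dropping to zero below the base temperature
# stands in for vernalisation over winter.
name: winter_wheat
EmrTSum: 100.0
DSRate1: 0.026
Fm: 7.0
QEff: 0.052
SpLAI: 0.0201
E_Leaf: 0.78
E_Stem: 0.78
E_SOrg: 0.75
r_Leaf: 0.010
r_Stem: 0.010
r_SOrg: 0.005
MaxPen: 210.0
MxNH4Up: 2.5e-7
MxNO3Up: 2.5e-7
SpRtLength: 100.0
C_per_N_slow_residue: 100.0
pet_factor_by_DS: [[0.0, 1.0], [1.0, 1.2], [2.0, 1.1]]
LeafAIMod_by_DS: [[0.0, 0.8], [0.5, 0.9], [1.0, 0.7], [2.0, 0.5]]
defaults:
  DSRate2: 0.025
  dev_temp_base: 0.0
  dev_temp_plateau: 20.0
  photo_temp_knots: [[0.0, 0.0], [10.0, 0.8], [20.0, 1.0], [35.0, 1.0], [42.0, 0.0]]
  photo_ds_knots: [[0.0, 1.0], [1.0, 1.0], [2.0, 0.6]]
  extinction_coefficient: 0.6
  q10_maintenance: 2.0
  maintenance_t_ref: 20.0
  root_penetration_rate: 1.2
  root_depth_fraction: 0.95
  aom_partition_slow: 0.5
  dm_carbon_fraction: 0.45
  partitioning_by_DS:
    - [0.0, 0.45, 0.35, 0.20, 0.00]
    - [0.5, 0.30, 0.40, 0.30, 0.00]
    - [1.0, 0.10, 0.10, 0.35, 0.45]
    - [1.3, 0.05, 0.00, 0.10, 0.85]
    - [2.0, 0.00, 0.00, 0.00, 1.00]
  n_conc_by_DS:
    leaf: [[0.0, 0.050], [1.0, 0.035], [2.0, 0.015]]
    stem: [[0.0, 0.035], [1.0, 0.015], [2.0, 0.006]]
    sorg: [[0.0, 0.022], [2.0, 0.020]]
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
  C_per_N_slow_residue: literature
  pet_factor_by_DS: literature
  LeafAIMod_by_DS: calibrated
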