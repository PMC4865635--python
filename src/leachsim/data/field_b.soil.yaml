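# Sandier profile, field B (straw removed), Luancheng, North China Plain.
# Organic-matter columns (humus, pool split, C/N) shared with field A.
name: field_b
horizons:
  - depth_top: 0.0
    depth_bottom: 20.0
    Ksat: 4.65
    theta_sat: 0.45
    theta_res: 0.06
    alpha: 0.004
    n: 1.252
    l: 1.75
    humus: 1.5
    SOM_fractions: [0.48, 0.42, 0.10]
    C_per_N: 10.0
    clay: 0.05
  - depth_top: 20.0
    depth_bottom: 40.0
    Ksat: 2.5
    theta_sat: 0.42
    theta_res: 0.01
    alpha: 0.004
    n: 1.23
    l: 1.23
    humus: 0.5
    SOM_fractions: [0.42, 0.42, 0.16]
    C_per_N: 11.0
    clay: 0.14
  - depth_top: 40.0
    depth_bottom: 110.0
    Ksat: 1.0
    theta_sat: 0.40
    theta_res: 0.05
    alpha: 0.003
    n: 1.288
    l: 1.05
    humus: 0.5
    SOM_fractions: [0.25, 0.25, 0.50]
    C_per_N: 12.0
    clay: 0.14
  - depth_top: 110.0
    depth_bottom: 210.0
    Ksat: 0.1
    theta_sat: 0.41
    theta_res: 0.15
    alpha: 0.002
    n: 1.25
    l: 1.15
    humus: 0.05
    SOM_fractions: [0.0, 0.0, 1.0]
    C_per_N: 12.0
    clay: 0.14
provenance:
  Ksat: calibrated
  theta_sat: measured
  theta_res: measured
  alpha: calibrated
  n: calibrated
  l: calibrated
  humus: measured
  SOM_fractions: calibrated
  C_per_N: default
  clay: measured
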