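# Silty loam profile, field A (straw incorporated), Luancheng, North China
# Plain.  Hydraulics: calibrated van Genuchten-Mualem set; humus and pool
# split from the turnover parameterisation.  Horizon boundary between the
# third and fourth horizon set at 110 cm (configurable).
name: field_a
horizons:
  - depth_top: 0.0
    depth_bottom: 20.0
    Ksat: 1.56          # cm/h
    theta_sat: 0.39
    theta_res: 0.06
    alpha: 0.008        # 1/cm
    n: 1.332
    l: 1.45
    humus: 1.5          # mass %
    SOM_fractions: [0.48, 0.42, 0.10]   # slow, fast, inert
    C_per_N: 10.0
    clay: 0.17
  - depth_top: 20.0
    depth_bottom: 40.0
    Ksat: 10.3
    theta_sat: 0.44
    theta_res: 0.01
    alpha: 0.009
    n: 1.248
    l: -1.26
    humus: 0.5
    SOM_fractions: [0.42, 0.42, 0.16]
    C_per_N: 11.0
    clay: 0.30
  - depth_top: 40.0
    depth_bottom: 110.0
    Ksat: 22.3
    theta_sat: 0.43
    theta_res: 0.12
    alpha: 0.005
    n: 1.186
    l: 0.72
    humus: 0.5
    SOM_fractions: [0.25, 0.25, 0.50]
    C_per_N: 12.0
    clay: 0.30
  - depth_top: 110.0
    depth_bottom: 210.0
    Ksat: 0.12
    theta_sat: 0.41
    theta_res: 0.12
    alpha: 0.002
    n: 1.188
    l: 0.88
    humus: 0.05
    SOM_fractions: [0.0, 0.0, 1.0]
    C_per_N: 12.0
    clay: 0.30
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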