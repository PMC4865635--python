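# Full parameter set for field A (straw incorporated), Luancheng, NCP.
name: ncp_field_a
field: A
soil: field_a.soil.yaml
crops:
  maize: pioneer_maize.crop.yaml
  winter_wheat: winter_wheat.crop.yaml
turnover: turnover.yaml
deposition: deposition.yaml
volatilisation: volatilisation.yaml
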