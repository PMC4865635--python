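# Full parameter set for field B (straw removed), Luancheng, NCP.
name: ncp_field_b
field: B
soil: field_b.soil.yaml
crops:
  maize: pioneer_maize.crop.yaml
  winter_wheat: winter_wheat.crop.yaml
turnover: turnover.yaml
deposition: deposition.yaml
volatilisation: volatilisation.yaml
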