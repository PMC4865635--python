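# Atmospheric nitrogen deposition for the Luancheng station weather file:
# wet deposition as concentration in rain (ppm = mg N per litre), dry
# deposition as an annual areal rate spread over the year.
wet_nh4: 7.5    # ppm NH4-N in precipitation
dry_nh4: 10.0   # kg N / ha / y
wet_no3: 2.5    # ppm NO3-N in precipitation
dry_no3: 5.0    # kg N / ha / y
provenance:
  wet_nh4: literature
  dry_nh4: literature
  wet_no3: literature
  dry_no3: literature
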