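# Ammonia volatilisation as a fraction of the urea-N dressing, increasing
# with the amount applied (larger dressings raise soil pH more).  Linear
# from (0, 0) below the first knot, piecewise linear between knots,
# constant above the last.
knots:
  - [50.0, 0.05]
  - [100.0, 0.10]
  - [150.0, 0.12]
  - [200.0, 0.15]
  - [300.0, 0.17]
provenance:
  knots: calibrated
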