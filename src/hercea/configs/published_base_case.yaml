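# Published deterministic base-case totals per strategy (2012 euros;
# discounted, half-cycle-corrected) from the original evaluation this
# package re-implements.  Reporting-layer inputs for validating the
# incremental statistics; not model output.  The trial scenario's per-arm
# QALYs were published only as an increment.
real_world:
  trastuzumab: {cost: 243216, ly: 19.180, qaly: 13.930}
  control: {cost: 239657, ly: 18.331, qaly: 13.103}
guideline:
  trastuzumab: {cost: 224443, ly: 18.511, qaly: 13.527}
  control: {cost: 218948, ly: 17.613, qaly: 12.666}
trial:
  trastuzumab: {cost: 253666}
  control: {cost: 265116}
  delta_qaly: 0.993
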