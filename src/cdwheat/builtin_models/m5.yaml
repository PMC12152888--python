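id: M5
kind: log_linear
response: cd_wheat
response_transform: log10
terms:
  - {feature: cd_msm, transform: log10, coefficient: 0.572}
  - {feature: ph, transform: identity, coefficient: 0.106}
intercept: -0.257
response_units: mg/kg
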