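id: M1
kind: log_linear
response: cd_wheat
response_transform: log10
terms:
  - {feature: cd_total, transform: log10, coefficient: 0.906}
intercept: -0.718
response_units: mg/kg
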