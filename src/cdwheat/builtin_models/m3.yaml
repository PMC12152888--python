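id: M3
kind: bcf_quadratic
response: cd_wheat
a: 0.014
b: -0.236
c: 1.113
ph_domain: [3.97, 8.55]
response_units: mg/kg
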