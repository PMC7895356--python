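name: three-factor scenario
top: NA
nodes:
- id: NA
  label: Non-adherence
  kind: top
  gate: OR
  children:
  - FORG
  - SIDE
  - OTHER
- id: FORG
  label: Forgetfulness
  kind: basic
  rate:
    form: constant
    rate: 0.006
- id: SIDE
  label: Side effects
  kind: basic
  rate:
    form: constant
    rate: 0.004
- id: OTHER
  label: Other factors
  kind: basic
  rate:
    form: constant
    rate: 0.01
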