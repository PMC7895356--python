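name: COVID-19 antiviral case study
description: Hypothetical 10-day out-patient antiviral regimen, 1000 participants
top: NA
nodes:
- id: NA
  label: Non-adherence to the medication regimen
  kind: top
  gate: OR
  children:
  - SocRel
  - PatRel
  - ConRel
  - HeaRel
  - TheRel
- id: SocRel
  label: Social/economic-related factors
  kind: intermediate
  gate: OR
  children:
  - SocSup
  - HeaAcc
- id: PatRel
  label: Patient-related factors
  kind: intermediate
  gate: OR
  children:
  - NoMed
  - Forgot
  - Other
- id: ConRel
  label: Condition-related factors
  kind: intermediate
  gate: OR
  children:
  - NoSym
- id: HeaRel
  label: Healthcare-related factors
  kind: intermediate
  gate: OR
  children:
  - ClinImp
  - NoTab
  - DelSys
  - PriKno
- id: TheRel
  label: Therapy-related factors
  kind: intermediate
  gate: OR
  children:
  - SidEff
- id: DelSys
  label: Medicine delivery system failure
  kind: intermediate
  gate: AND
  children:
  - IctSys
  - ManSys
- id: SocSup
  label: Limited social support
  kind: basic
  rate:
    form: age_stratified
    bands:
    - label: <25
      rate: 0.0004138
      weight: 0.3333333333333333
    - label: 25-45
      rate: 0.0001379
      weight: 0.3333333333333333
    - label: '>45'
      rate: 0.0002069
      weight: 0.3333333333333333
- id: HeaAcc
  label: Limited healthcare access
  kind: basic
  rate:
    form: constant
    rate: 0.00012
- id: NoMed
  label: Choice not to take medication
  kind: basic
  rate:
    form: constant
    rate: 0.0003448275862068965
- id: Forgot
  label: Forgetfulness
  kind: basic
  rate:
    form: constant
    rate: 0.004896551724137932
- id: Other
  label: Other patient-related factors
  kind: basic
  rate:
    form: constant
    rate: 0.005001642036124794
- id: NoSym
  label: No symptoms
  kind: basic
  rate:
    form: constant
    rate: 0.00593103448275862
- id: ClinImp
  label: Clinical improvement
  kind: basic
  rate:
    form: constant
    rate: 0.00013793103448275863
- id: NoTab
  label: Limited tablets (2-day resupply delay)
  kind: basic
  rate:
    form: constant
    rate: 0.0003448275862068965
- id: SidEff
  label: Side effects of the medication
  kind: basic
  rate:
    form: constant
    rate: 0.008315270935960592
- id: PriKno
  label: Lack of prior adherence knowledge
  kind: basic
  rate:
    form: linear_decay
    initial_rate: 0.00015
    decay_fraction_per_day: 0.08
- id: IctSys
  label: ICT medicine-delivery system
  kind: basic
  rate:
    form: repairable
    failure_rate: 8.12e-05
    mean_repair_time: 4.0
- id: ManSys
  label: Manual medicine-delivery system
  kind: basic
  rate:
    form: repairable
    failure_rate: 5.34e-05
    mean_repair_time: 2.0
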