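# Two-field meningioma-like pMBRT plan, ctc 4 mm (slit patterns offset by
# ctc/2 between fields).
name: meningioma_ctc4
seed: 20200427
grid:
  shape: [97, 9, 400]
  spacing: [0.5, 0.5, 0.5]
  origin: [-24.0, -2.0, 0.0]
fields:
  - technique: pmbrt
    config: meningioma_field1_ctc4
    overrides: {slit_offset: 0.0}
  - technique: pmbrt
    config: meningioma_field1_ctc4
    overrides: {slit_offset: 2.0}
ptv:
  lower: [-6.5, -100.0, 70.0]
  upper: [6.5, 100.0, 90.0]
organs:
  brain:
    lower: [-20.0, -100.0, 2.0]
    upper: [20.0, 100.0, 55.0]
depths: [1.0, 10.0, 20.0, 40.0, 60.0, 80.0, 190.0]
rbe:
  model: mcnamara
  dose_per_fraction: 2.0
  alpha_beta_target: 10.0
  alpha_beta_normal: 3.0
gamma_reference: true
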