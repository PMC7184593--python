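# Three-field glioma-like pMBRT plan, ctc 6 mm (slit patterns offset by
# ctc/3 between fields).
name: glioma_ctc6
seed: 20200427
grid:
  shape: [97, 9, 400]
  spacing: [0.5, 0.5, 0.5]
  origin: [-24.0, -2.0, 0.0]
fields:
  - technique: pmbrt
    config: glioma_field2_ctc6
    overrides: {slit_offset: 0.0}
  - technique: pmbrt
    config: glioma_field2_ctc6
    overrides: {slit_offset: 2.0}
  - technique: pmbrt
    config: glioma_field2_ctc6
    overrides: {slit_offset: 4.0}
ptv:
  lower: [-6.5, -100.0, 75.0]
  upper: [6.5, 100.0, 95.0]
organs:
  brain:
    lower: [-20.0, -100.0, 2.0]
    upper: [20.0, 100.0, 60.0]
depths: [1.0, 10.0, 20.0, 40.0, 60.0, 80.0, 190.0]
rbe: null
gamma_reference: false
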