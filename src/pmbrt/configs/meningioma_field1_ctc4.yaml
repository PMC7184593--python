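# Meningioma-like field, 4 mm centre-to-centre planar minibeams.
name: meningioma_field1_ctc4
ctc: 4.0
n_slits: 9
slit_axis: 0
slit_offset: 0.0
fwhm_model:
  - [0.0, 0.7]
  - [10.0, 0.7]
  - [20.0, 0.8]
  - [40.0, 1.2]
  - [60.0, 2.0]
  - [80.0, 2.3]
  - [200.0, 2.4]
halo_fraction_model:
  - [0.0, 0.065]
  - [20.0, 0.07]
  - [40.0, 0.08]
  - [60.0, 0.12]
  - [67.0, 0.35]
  - [73.0, 0.55]
  - [95.0, 0.60]
  - [200.0, 0.65]
halo_fwhm: 20.0
target_band: [70.0, 90.0]
noise_rel: 0.03
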