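# Glioma-like field, 6 mm centre-to-centre spacing (stronger spatial
# fractionation in normal tissue at the cost of target homogeneity).
name: glioma_field2_ctc6
ctc: 6.0
n_slits: 7
slit_axis: 0
slit_offset: 0.0
fwhm_model:
  - [0.0, 1.0]
  - [10.0, 1.1]
  - [20.0, 1.2]
  - [40.0, 1.6]
  - [60.0, 2.0]
  - [80.0, 3.1]
  - [200.0, 3.2]
halo_fraction_model:
  - [0.0, 0.07]
  - [20.0, 0.075]
  - [40.0, 0.08]
  - [60.0, 0.12]
  - [72.0, 0.35]
  - [78.0, 0.55]
  - [100.0, 0.60]
  - [200.0, 0.65]
halo_fwhm: 20.0
target_band: [75.0, 95.0]
noise_rel: 0.03
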