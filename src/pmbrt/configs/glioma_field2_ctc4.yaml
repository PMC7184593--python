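# Glioma-like field, 4 mm centre-to-centre planar minibeams.
# FWHM-vs-depth follows the measured beam-size column for this geometry
# (0.7 mm near the surface growing to ~2.2 mm at depth); halo fractions are
# calibration constants chosen so shallow valley doses land in the 5-7% of
# prescription band and the target region homogenises (PVDR ~1.0-1.2).
name: glioma_field2_ctc4
ctc: 4.0
n_slits: 9
slit_axis: 0
slit_offset: 0.0
fwhm_model:
  - [0.0, 0.7]
  - [10.0, 0.7]
  - [20.0, 0.9]
  - [40.0, 1.2]
  - [60.0, 1.7]
  - [80.0, 2.1]
  - [200.0, 2.2]
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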