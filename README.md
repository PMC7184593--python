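# pmbrt — proton minibeam treatment-plan evaluation

Proton minibeam radiation therapy (pMBRT) delivers spatially fractionated
dose through a multislit collimator: narrow planar beams (~0.7 mm FWHM at
the surface, broadening to ~2–3 mm at depth) spaced 4–6 mm centre to
centre.  Healthy tissue between the beams sees only a low *valley* dose,
while scattering and a spread-out Bragg peak (SOBP) merge the beams into a
quasi-homogeneous dose at a deep-seated target.  Evaluating such plans
needs metrics that conventional, flat-field dosimetry does not provide.

`pmbrt` is a Python library (plus a thin CLI) for medical-physics
researchers evaluating pMBRT-like dose distributions on voxelised grids:

* **Spatial fractionation** — per-peak peak-to-valley dose ratio (PVDR)
  from *topographic dose prominence*: each peak's prominence is the dose
  difference between the peak and its lowest enclosing contour line, and

      PVDR = peak dose / (peak dose − prominence)

  with the collection's uncertainty reported as the SD of the per-peak
  PVDRs.  Also valley dose and beam FWHM versus depth, and per-organ PVDR
  pooled over all lattice lines crossing a structure.
* **DVH metrics** — differential/cumulative DVHs, sigma-index (SD of the
  normalised differential DVH), D95, V93/V110 (strict inequalities), and
  the Monte-Carlo-style relative statistical uncertainty
  `sqrt(mean variance) / mean dose` over voxels above 90% of the maximum.
* **LET and RBE** — dose-averaged LET accumulation (energy-weighted mean
  of per-step LET) and two LET-dependent linear-quadratic RBE models
  (Wedenberg; McNamara), giving RBE and RBE-weighted dose grids with
  α/β = 10 Gy (target) / 3 Gy (normal tissue) at 2 Gy per fraction.
* **Gamma index** — local or global dose-difference / distance-to-agreement
  comparison (3%/3 mm default) with sub-voxel search and passing rates.
* **Synthetic fields** — a seeded analytic generator of minibeam-like dose
  and LET grids (Gaussian beam cores + scatter halo, NNLS-optimised SOBP,
  multiplicative MC-like noise) and seamless broad-beam comparison arms,
  so every stage can be exercised without Monte Carlo transport.

Grids are read and written as NRRD or MetaImage volumes (via SimpleITK);
doses are expressed in percent of the prescribed dose (D50 = 100%), LET in
keV/µm, lengths in mm.

## Worked example

```python
import dataclasses
import pmbrt

cfg = pmbrt.MinibeamPlanConfig.bundled("glioma_field2_ctc4")
cfg = dataclasses.replace(cfg, seed=1)
dose, let = pmbrt.generate_pmbrt_dose(cfg)   # % of prescription, keV/µm

print("depth_mm  fwhm_mm  pvdr_mean  pvdr_sd  valley_pct")
for depth in (10, 20, 40, 60):
    ps = pmbrt.pvdr_at_depth(dose, depth, slab_voxels=3, interior_only=True)
    print(f"{depth:8.0f}  {ps.fwhm:7.2f}  {ps.pvdr_mean:9.2f}  "
          f"{ps.pvdr_sd:7.2f}  {ps.valley_dose:10.2f}")

ptv = pmbrt.build_box_mask(dose, "PTV", (-6.5, -100, 75), (6.5, 100, 95))
stats = pmbrt.coverage_stats(dose, ptv)
peaks = pmbrt.pvdr_per_organ(dose, ptv, ctc=cfg.ctc)
print(f"\nPTV: mean {stats.mean_dose:.1f}%  D95 {stats.d95:.1f}%  "
      f"s-index {stats.s_index:.1f}%  PVDR {peaks.pvdr_mean:.2f} +- {peaks.pvdr_sd:.2f}")
```

prints

```
depth_mm  fwhm_mm  pvdr_mean  pvdr_sd  valley_pct
      10     0.70       5.18     3.93        7.08
      20     1.19       5.04     3.94        7.47
      40     1.26       4.72     3.66        8.49
      60     2.55       3.28     2.65       15.59

PTV: mean 91.9%  D95 79.2%  s-index 7.1%  PVDR 1.13 +- 0.07
```

Reading this: in shallow tissue the field is strongly fractionated — beams
of 0.7–1.3 mm FWHM with valley doses of ~7–8% of prescription and mean
PVDRs around 5 — while at the 75–95 mm target band the same field has
homogenised to a PVDR of 1.13 and a sigma-index of 7%.  Summing the plan's
three fields (offset slit patterns) homogenises further; with the bundled
three-field plan,

```python
report = pmbrt.evaluate_plan(pmbrt.PlanSpec.bundled("plan_glioma_ctc4"))
```

the summed PTV PVDR drops to 1.04 ± 0.02 and the s-index to 5.1%, below
every individual field (6.8–7.1%) — the multi-field homogenisation effect.
The same report carries per-organ DVH metrics, a depth table, RBE-weighted
dose summaries and a 3%/3 mm local gamma comparison of the noise-free
versus MC-noise seamless arms.

The CLI exposes the same steps:

```sh
pmbrt evaluate -c plan.yaml --seed 1 --out report/
pmbrt pvdr --dose dose.nrrd --depths 10,20,40 --out pvdr.csv
pmbrt gamma --reference tps.nrrd --evaluated mc.nrrd --out cmp
```

## Documentation

`docs/methods.md` describes the dose/LET models behind the synthetic
generator, the metric definitions and their numerical conventions
(prominence tie-breaking, DVH binning, gamma search), and the known
limitations of the desk-scale emulation.
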