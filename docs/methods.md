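# Methods

This note documents the models and numerical conventions behind `pmbrt`:
what the synthetic minibeam generator emulates (and what it does not), how
each metric is defined, and where genuinely open design choices were
resolved.

## Conventions

Arrays are indexed `[x, y, z]`; `z` is the beam depth axis, `x` the
fractionation (slit-normal) axis, `y` runs along the slit planes.  Voxel
indices are 0-based, positions are voxel centres, all lengths are mm.
Dose grids hold percent of the prescribed dose (D50 = 100%); LET grids
hold dose-averaged LET in keV/µm.  Two grids are congruent when shapes,
spacings and origins agree within 1e-6 mm; metrics refuse non-congruent
inputs rather than resampling.  The default lattice is 97 × 9 × 400 voxels
at 0.5 mm isotropic spacing (the standard scoring resolution for this kind
of Monte Carlo dosimetry); the odd lateral count puts slit centres on
lattice points, which keeps peak-line normalisation and FWHM measurements
free of half-voxel bias.

## Synthetic minibeam fields

The generator produces the statistical structure of collimated planar
proton minibeams without particle transport.  It is separable:

    dose(x, y, z) = SOBP(z) · lateral(x, z),   uniform along y.

**Depth dose.**  The pristine Bragg curve is a closed form — a rising
power-law plateau `0.35 + 0.20 (z/R)³` multiplied by a tanh distal
falloff, plus a Gaussian peak at range `R` whose width grows with range
(`σ = 0.35 + 0.012 R` mm, emulating straggling).  It peaks at `R` within
half a straggling width, has an entrance-to-peak ratio ≈ 0.23, and decays
below 1% of the peak within a few mm beyond the range.  An SOBP is a
non-negative least-squares (NNLS) weighted sum of pristine curves; by
default layers are spaced 2 mm across the target band and the weights
minimise squared deviation from a flat plateau, giving in-band ripple
around ±2%.  As in real SOBPs the distal layer dominates, so the weight
vector is *not* symmetric under range reversal — the solver is instead
exactly permutation-equivariant.

**Lateral structure.**  Each slit contributes a double Gaussian: a core of
depth-dependent FWHM (piecewise-linear table, e.g. 0.7 mm near the surface
to 2.2 mm at 80–90 mm for the 4 mm ctc configuration) and a broad scatter
halo (20 mm FWHM) carrying a depth-dependent fraction *h* of the
amplitude.  Gaussians are amplitude-normalised so an isolated core peak
equals 1.  The halo fractions in the bundled configs are calibration
constants — chosen once so that shallow valley doses land in the 5–7% of
prescription band and the target region homogenises to PVDR ≈ 1.0–1.2 —
and live in the YAML files, not in code, so the physics assumptions stay
inspectable.  Fields are normalised so the mean dose on the central peak
lattice line inside the target band is 100%.

**Noise and LET.**  MC-like noise is multiplicative Gaussian
(`dose × (1 + 0.03 N)`, clipped at zero), seeded and reproducible.  The
LET grid is parametric: a primary-proton LET versus depth table plus a
valley offset scaled by `1 − core(x,z)/max`, so beam axes carry the
primary LET and inter-beam valleys carry 1–3 keV/µm more — valleys are
populated only by scattered and secondary particles, which are slower and
densely ionising.

**What the generator does not emulate.**  No nuclear interactions, no
patient heterogeneity, no collimator scatter or spot-map structure, and no
gantry geometry: multi-field plans are emulated by laterally offsetting
the slit pattern between fields (ctc/n_fields), which reproduces the
homogenisation that summing differently-angled fields provides.  Because
the lateral comb is amplitude-normalised at every depth, entrance peak
doses follow the SOBP entrance level rather than exceeding prescription as
fluence-concentrated physical beams do; shallow PVDRs of the synthetic
fields are therefore lower (≈5) than measured minibeam data (≈9–19), while
valley-dose levels, FWHM growth, target homogenisation and all
direction-of-effect behaviours (wider ctc → higher PVDR; field summation →
lower s-index) are preserved.  Tests passing on these fields validate the
*metrics*, not a transport model.

## Fractionation metrics

**Prominence and PVDR.**  Peaks are local maxima (plateau centres for flat
tops) with topographic prominence: the height above the higher of the two
lowest saddles separating the peak from terrain of equal or greater
height, or from the profile boundary (boundaries act as saddles).
Stopping at *equal* terrain is a deliberate tie convention: the interior
peaks of an idealised periodic comb are exactly equal in float64, and
under a strictly-greater rule they would all merge and be measured against
the field edge instead of their own valleys.  Each summit of a tied pair
is thus measured to its adjacent saddle.  Per peak,
`PVDR = peak/(peak − prominence)`; a zero baseline yields an `inf`
sentinel with a warning; a flat profile yields an empty peak set flagged
`no_fractionation` with PVDR reported as 1.  The default prominence
threshold is 2% of the profile maximum — below physical minibeam
prominences, above residual noise excursions after slab averaging.

**Aggregation.**  `pvdr_at_depth` analyses the central lattice line at a
depth (optionally averaged over a slab of depth planes; the depth-table
default is 3 planes = 1.5 mm); the valley dose is the mean of the
inter-peak minima (robust to noise, unlike the global minimum) and the
FWHM is that of the central peak, measured at half of
`peak − baseline` with `baseline = peak − prominence` and linear
interpolation between samples — a constant background therefore does not
bias the width.  For halo-dominated depths (target region), the central
peak's prominence reaches far down the lateral envelope and the measured
"width" spans the whole dome; FWHM is meaningful where fractionation is
pronounced.  `pvdr_per_organ` runs the peak finder on every contiguous
in-mask segment of at least 2 ctc along the fractionation axis and pools
all peaks (mean and SD over the pooled collection, rather than averaging
per-line means; the pooled set is what "the PVDR of an organ's peaks"
denotes).  The `interior_only` flag drops the outermost peak on each side,
whose outer saddle is the field edge.

## DVH metrics

DVHs use equal voxel weighting and 0.1% bins (below the precision at which
homogeneity indices are reported).  The cumulative curve is the exact
suffix sum of the integer bin counts, so it equals 1 at dose 0 and 0 above
the maximum dose.  The sigma-index is the SD of the normalised
differential DVH — it matches the voxel-wise SD to within one bin width.
D95 is computed directly from the voxel doses as the inverted-CDF 5th
percentile (the largest dose level received by ≥95% of the volume); this
is the zero-bin-width limit of interpolating the cumulative curve and is
free of binning bias.  V93/V110 use strict inequalities (`< 93%`,
`> 110%`).  The MC uncertainty estimator selects voxels above 90% of the
maximum dose and returns `sqrt(mean variance)/mean dose` as a fraction;
with per-voxel variance estimated across seeded replicate generations it
recovers the injected 3% noise to well within ±0.5 percentage points.

## LET and RBE

Dose-averaged LET is accumulated as `Σ(energy·LET) / Σ(energy)` per voxel;
voxels with zero deposited energy are undefined, excluded from RBE
statistics and counted.  Both RBE models are linear-quadratic with LET
entering the α term (and, for McNamara, the β term):

    RBE_Wedenberg = (1/2D)(√((α/β)² + 4D(α/β + 0.434·LET) + 4D²) − α/β)

    RBE_McNamara = (1/2D)(√((α/β)² + 4D(α/β)(0.999064 + (0.35605/(α/β))·LET)
                   + 4D²(1.1012 + 0.0038703·√(α/β)·LET)²) − α/β)

with D in Gy and LET in keV/µm (the coefficients carry the units).
Wedenberg reduces exactly to 1 at LET = 0; McNamara tends to
`1.1012 + 0.0038703 √(α/β) LET` at high dose and is ≥1 over the clinical
domain; both are monotone non-decreasing in LET.  Relative-dose grids are
anchored to physical dose by mapping 100% to the fraction dose (default
2 Gy) before evaluation, with α/β = 10 Gy inside the target mask and 3 Gy
in normal tissue.  Voxels with zero dose, undefined LET, or outside both
masks pass their physical dose through with RBE 1.

## Gamma comparison

For each reference voxel above the low-dose cutoff (default 10% of the
reference maximum — local-mode normalisation diverges at near-zero doses),
the gamma index minimises
`√((Δdose/(tol·norm))² + (distance/DTA)²)` over evaluated positions on a
sub-voxel lattice (step DTA/10, radius 3·DTA, trilinear interpolation;
positions outside the grid are skipped).  Offsets are visited in order of
increasing distance, and the search stops once the distance term alone
exceeds every voxel's running minimum — an exact optimisation, verified
against a full exhaustive search to 1e-6.  `local` mode normalises by the
reference voxel dose (the configuration used for plan validation),
`global` by the reference maximum.  A voxel passes when γ < 1 strictly.

## Plan pipeline

A plan is a list of fields on a common lattice.  Fields are generated
individually (each normalised to 100% in the target band) and the summed
plan is their mean — doses are summed *before* metrics, which is what
produces the multi-field homogenisation (the summed s-index falls below
every individual field's).  Per-field seeds derive from the master seed
and the field configuration content, so reports are byte-reproducible and
invariant under field reordering.  The summed LET is the dose-weighted
mean of the per-field LET grids.  The report contains per-field and summed
PTV metrics, per-organ coverage, a PVDR/valley/FWHM depth table (computed
on the first minibeam field, matching the field-wise convention for such
tables), optional RBE summaries, and an optional 3%/3 mm local gamma
comparison between a noise-free and an MC-noise seamless arm.

## Problem sizes

Default study conditions: 97 × 9 × 400 voxel grids (24 × 4.5 × 200 mm) for
minibeam fields, 9 slits at 4 mm ctc (7 at 6 mm), target band 75–95 mm
(glioma-like) or 70–90 mm (meningioma-like), 3% voxel noise; uncertainty
recovery uses ten 64 × 64 × 128 replicates.  A full three-field plan
evaluation, including gamma and RBE, runs in a few seconds on one core.

## Known limitations

* The generator is separable and amplitude-normalised; it reproduces
  valley-dose levels and homogenisation trends but not absolute entrance
  PVDR magnitudes of measured minibeam data (see above).
* Prominence-based PVDR assigns the global lateral maximum a prominence
  measured to the field edge; on dome-shaped envelopes this inflates that
  single peak's PVDR and the per-depth SD.  This is inherent to the
  topographic definition; `interior_only` and pooled per-organ statistics
  mitigate it.
* FWHM from `pvdr_at_depth` is unreliable where the halo dominates the
  comb (target depths); it is intended for the fractionated region.
* Masks are axis-aligned boxes in the bundled plans; arbitrary masks are
  supported but no DICOM-RT structure input exists.
* `measure_fwhm` walks through higher neighbouring terrain if the half
  level lies below an inter-peak saddle; for well-separated minibeam peaks
  this does not occur.
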