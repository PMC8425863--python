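# Methods

This note documents the models, parameter choices and numerical
conventions behind `ddalab`, and what the phantom study can and cannot
say about patient data.

## Coordinate and field conventions

Volumes are axis-aligned; arrays are indexed (i, j, k) along world
x/y/z, voxel centers at `origin + index · spacing` (mm).  One
displacement-field convention is used everywhere: a field lives on the
*fixed* (daily) lattice and maps a daily-frame point x to the
planning-frame point x + u(x).  Warping the planning CT onto the daily
frame is therefore a pull-back with no inversion; mapping dose back onto
the planning CT uses the numerical inverse, computed per planning voxel
by the fixed-point iteration v ← −u(y + v) (tolerance 0.01 mm, max 50
iterations).  Voxels whose composition residual ‖u(y+v)+v‖ exceeds ten
times the tolerance, or whose iterates leave the field's domain, are
flagged unreliable and excluded from dose statistics rather than
extrapolated.

## The phantom

The pelvis is analytic: an elliptical-cylinder body (radii 75 × 65 mm,
0 HU) containing ellipsoidal prostate (CTV), seminal vesicles, bladder,
penile bulb and femoral heads, a tubular rectum, and a sacral bone site;
background −1000 HU, bone 500–700 HU.  The PTV is the CTV ellipsoid
expanded 5 mm.  The default lattice is 64 × 64 × 48 at 2.5 mm — a
deliberately desk-scale problem; the daily image is the same lattice
cropped to the bounding box of a cylindrical field of view (radius
60 mm, length 100 mm), with out-of-FOV voxels carried in a dedicated
flag mask rather than a sentinel HU value.

Soft tissue carries a smooth sinusoidal texture (amplitude 12 HU,
wavelength 40 mm, three fixed non-axis-aligned plane waves) that is part
of the anatomy and deforms with it.  Real CT interiors are not flat;
without interior intensity structure, deformable registration of the
interior is ill-posed and any recovery claim would be meaningless.

Daily deformations are a rigid couch offset (per-axis Gaussian, SD
2 mm) plus 2–4 Gaussian displacement bumps (amplitude up to 4 mm, σ
18–28 mm) anchored near the bladder and rectum — the mobile soft tissue.
The analytic form is kept, so exact displacement is available at any
continuous point; fields whose Jacobian determinant leaves [0.5, 2] are
rejected.  Daily images are rendered by evaluating the analytic HU model
at deformation-mapped voxel centers, which makes the daily ground-truth
masks exact re-voxelizations rather than interpolated warps.

The two reconstruction variants render the *same* deformed anatomy and
differ only in degradation: `fdk_like` adds 40 HU Gaussian noise and a
50 HU parabolic cupping deficit (the dominant scatter artifact of
filtered back-projection); `iterative_like` adds 10 HU noise and 5 HU
cupping.  These magnitudes are typical of clinical FDK versus
scatter-corrected iterative CBCT and are fixed study conditions, not
tuning knobs.

Raters are simulated per voxel: label 1 with probability = sensitivity
inside the truth, probability = 1 − specificity in a bounded review
region outside it (default: truth dilated 3 voxels), independent across
raters and voxels.  An optional largest-connected-component cleanup
exists behind a recorded flag and defaults to off, so the nominal error
rates are preserved exactly — required for the STAPLE recovery check.
The default rater model (sensitivity 0.90, specificity 0.95, 4 raters)
stands in for the three-to-five blinded physicians of a contouring
study.

## Registration

The chain is translation → Euler rigid → affine → B-spline, each stage
maximizing Mattes mutual information (32 bins, 50 % regular sampling,
seeded) restricted to the FOV mask, on an image pyramid (linear stages:
shrink 4/2/1; B-spline: 2/1).  Each new stage is optimized with the
accumulated earlier stages applied as the moving initial transform, so
the latest stage acts first on the fixed-grid point — the standard
sequential-refinement composition.  Optimizers: regular-step gradient
descent for the linear stages, gradient-descent-with-line-search for the
B-spline (20 iterations), scales from physical shift.

Both images are windowed to [−100, 120] HU before optimization.  This is
standard soft-tissue windowing, and it matters: with the full HU range,
Mattes MI can be *increased* by deformations that steer samples away
from bone and air, shrinking the adaptive intensity range and sharpening
the joint histogram — on an already-aligned pair the unwindowed B-spline
drifts by ~10 mm while "improving" the metric.  Windowing removes the
exploitable range.

B-spline smoothness is governed by the control-point spacing (40 mm
final grid) and the multi-resolution schedule; no explicit
bending-energy term is applied (the config records the weight for
documentation, but it is inactive).  A stage whose result worsens the
audited histogram MI by more than 0.02 nats is discarded and the chain
falls back to the previous stages — on a perfectly aligned pair this
correctly leaves the identity.  A B-spline whose Jacobian determinant is
non-positive inside the FOV is flagged `folded`.

The demons variant applies the linear chain first, runs the classic
demons update with Gaussian field smoothing (σ 1.5 voxels) between
iterations, and composes the residual field with the linear transform.

Registration quality is scored against the analytic truth as the mean
displacement error at 50 random in-FOV voxel centers ("landmark error").
On noiseless renderings the chain recovers the deformation to ~0.5 mm
(0.2 voxels); with the default degradations the FDK-like variant's error
is consistently two-to-three times the iterative-like variant's — the
mechanism the whole study turns on.

## Dose

The dose engine is parametric, not physics-based: full prescription
inside the target, Gaussian penumbra exp(−d²/2σ²) with σ = 5 mm outside
(distance-transform based).  The default plan is 2.00 Gy × 39 fractions
to the PTV.  The plan is fixed in machine coordinates: the daily target
is the planning PTV placed rigidly by the treatment-record couch shift,
identical for both variants.  The dCT enters only through a weak
attenuation-like modulation, × (1 − 0.05 · smoothed HU/1000) — so the
two variants' daily doses are nearly identical before mapping, and every
sizeable downstream difference is caused by registration geometry, as in
a same-plan clinical comparison.  Dose mapping is plain trilinear
interpolation of dose through the inverse field; no mass/energy
remapping is attempted, a declared limitation.  Accumulation is a
voxelwise sum with per-voxel valid-fraction counts; normalized DDA
divides by the fraction count; full-course projection scales by
total/analyzed fractions.

Difference statistics (signed mean, signed SD, max absolute) are
evaluated over the daily FOV before mapping and over the mutually valid
mapped region on the planning lattice after mapping.

## DVH and constraints

Cumulative DVHs count voxels exactly (volume = count × voxel volume)
with a 0.05 Gy default bin; DX% inverts the curve with linear
interpolation between edges.  The 0.035 cc near-extremes never use the
binned curve: voxel doses are sorted exactly and the dose at the
fractional-voxel cut is linearly interpolated — the hottest-volume dose
is the interpolated minimum over the hottest 0.035 cc, symmetrically for
the coldest.  Percent goals resolve against the full-course
prescription.  A constraint on a structure absent from the set yields an
NA row rather than an error.

## Contour agreement and statistics

A "contour" is the 6-connectivity boundary voxel set of a mask, with
world-mm distances.  DSC is voxel-count Dice; MCD is the distance
between centers of mass; HD is computed on boundary point sets via KD
trees, exactly matching the brute-force pairwise definition, in directed
and symmetric modes (symmetric is the pipeline default and is recorded
per row).  STAPLE is the standard EM: spatially uniform prior equal to
the mean rater foreground fraction over the review region, voxelwise
posterior E-step, sensitivity/specificity M-step, log-likelihood tracked
and checked non-decreasing; consensus thresholds the posterior at 0.5.
Degenerate raters (identical to the review region, or empty) have the
unidentified parameter clamped with a warning.

Paired differences are iterative-variant metric minus FDK-variant
metric (positive DSC difference = improvement; negative MCD/HD
difference = improvement).  The pairing unit for the one-tailed paired
t-test (t = mean/(sd/√n), sample SD, Student reference) is the phantom
replicate — each replicate seed stands in for a patient; the direction
of the alternative is always explicit in the call.  Raters for a given
replicate and day are drawn once and shared by both variants, so the
paired differences isolate registration rather than rater sampling.

## Study defaults and problem sizes

The study runs 10 replicates × 1 day × 2 variants on the 64³-scale
phantom — about 40 registrations plus inversion, mapping and analytics,
chosen so the full analysis and its test suite complete comfortably on a
single CPU.  All randomness derives from the single study seed through
fixed integer stream offsets (per-day deformation, per-style noise,
per-replicate registration sampling, rater draws).

## What passing does and does not show

The phantom reproduces the study's two central qualitative findings:
voxel dose differences between variants are orders of magnitude larger
after deformable mapping than before, co-located with the dose gradient;
and the cleaner variant yields significantly better mapped-contour
agreement (positive prostate DSC difference, one-tailed p < 0.05 across
replicates).  It does not reproduce patient-scale magnitudes: real CBCT
noise is structured (scatter, lag, motion), real anatomy deforms with
sliding and content change that Gaussian bumps do not model, the dose
engine has no heterogeneity or beam physics, and the FOV/deformation
sizes are assumptions recorded in the config, not measured values.  The
Hausdorff-difference direction is additionally fragile here: simulated
raters make the STAPLE consensus boundary ragged at the voxel scale, and
the max-distance metric is dominated by that raggedness rather than by
registration quality — the package reports the metric and its p-value
honestly rather than asserting a direction for it.
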