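# ddalab — deformable dose accumulation on a synthetic pelvis phantom

Adaptive radiotherapy needs to know the dose a patient *actually*
received over a fractionated course.  Deformable dose accumulation (DDA)
answers this by deformably registering the planning CT (pCT) to each
day's cone-beam CT (CBCT), computing the day's dose on the deformed CT
(dCT), mapping it back through the displacement field (DVF) onto the
planning anatomy, and summing:

```
DDA(y) = Σ_f  D_f( y + v_f(y) ),        v_f = inverse of the day-f DVF
```

The clinically loaded question is how sensitive that whole chain is to
daily image quality: CBCTs reconstructed with filtered back-projection
("FDK-like": noisy, cupping artifact) versus iterative reconstruction
("iterative-like": clean) show the *same* anatomy, yet registration —
and everything downstream of it — responds differently.  `ddalab`
implements the full chain and the three-level comparison between the two
variants:

* **Level A** — voxelwise dose differences between variants, before
  mapping, after mapping, and on the normalized (per-fraction) DDA;
* **Level B** — DVH constraint tables (Dmean, D95%, D50%, D15%, D5%, and
  the 0.035 cc near-min/max doses) for the plan and both accumulated
  doses projected to the full course;
* **Level C** — agreement of DIR-mapped contours with a STAPLE consensus
  of simulated raters: Dice coefficient (DSC), center-of-mass distance
  (MCD), Hausdorff distance (HD), their paired iterative−FDK differences,
  and one-tailed paired t-tests across phantom replicates.

Patient CBCT data of this kind is not public, so the package ships a
deformable pelvis phantom (`ddalab.phantom`): analytic organs with CT
texture, ground-truth daily deformations with exact continuous
displacements, a cylindrical daily field of view smaller than the pCT,
two reconstruction-quality renderings of identical anatomy, and raters
with known sensitivity/specificity.  Every downstream claim is testable
against analytic ground truth.

The registration chain is the classic four-stage design — translation →
rigid (Euler) → affine → B-spline, all maximizing Mattes mutual
information on an image pyramid, restricted to the field of view — plus a
demons variant, built on SimpleITK.  Field inversion (fixed-point),
dose warping, DVH metrics, contour metrics, and the STAPLE EM are
implemented in the package.

## Worked example

```python
from ddalab.pipeline import StudyConfig, run_study

report = run_study(StudyConfig(n_replicates=2, n_days=1, seed=1))
print(report.level_a[["stage", "max_abs_gy"]])
```

prints (replicate 0 then 1; values in Gy):

```
            stage  max_abs_gy
0  before_mapping    0.000402
1   after_mapping    0.419689
2  normalized_dda    0.419689
3  before_mapping    0.000363
4   after_mapping    0.455919
5  normalized_dda    0.455919
```

Before dose mapping, the two variants' daily doses are nearly identical —
the plan is fixed in machine coordinates and the two dCTs differ only in
soft tissue.  After mapping each dose through its own variant's inverse
DVF, the maximum voxel difference jumps three orders of magnitude, to
~0.4 Gy on a 2 Gy fraction, concentrated in the penumbra where the dose
gradient is steepest.  `report.level_c_differences` shows the paired
contour metrics (e.g. prostate DSC difference ≈ +0.03–0.04 in favor of
the cleaner variant), and `report.t_tests` their one-tailed p-values.

A thin CLI wraps the same functions: `ddalab phantom`, `ddalab register`,
`ddalab study` (see `--help`).

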