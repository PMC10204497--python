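# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations of `mrsipipe`, in the spirit of a model-documentation
page: what the pipeline assumes, which knobs matter, and what the synthetic
tests do and do not demonstrate about real data.

## Volumes and geometry

All volumes are 3D lattices with per-axis spacing (mm), a world origin, and
an orthonormal direction matrix; world coordinates follow
`world = origin + direction @ (index * spacing)` with 0-based indices. Every
physical quantity (contour volumes in cc, Hausdorff distances in mm) is
derived from this geometry, so the pipeline is agnostic to the voxel
dimensions of the input maps. Two grids are considered identical when
spacing and origin agree within 1e-4 mm and direction cosines within 1e-6 —
wide enough to absorb header round-off, tight enough to catch genuine
mismatches.

NIfTI is the canonical on-disk format. DICOM series import is read-only:
slices are sorted by their position along the slice normal and a gap or
irregular spacing larger than 1e-3 of the median gap is a format error
naming the offending slice. Rasterized masks only; RT-structure-set
contours are out of scope.

## Contouring

The abnormality contour is `ratio >= k * mean(ratio | NAWM)` restricted to
the spectral-quality support, with the boundary inclusive. Parameters:

| parameter | default | units | rationale |
|---|---|---|---|
| ratio multiplier k | 2.0 | — | twice-normal Cho/NAA is the established metabolic target definition |
| linewidth cutoff | 18.0 | Hz | voxels with broader metabolite peaks carry unreliable fits; removal is strict (> 18 Hz removed, 18.0 retained) |
| min NAWM voxels | 50 | count | a mean over fewer defined NAWM voxels makes the threshold unstable; the operation fails rather than guessing |

Undefined voxels are NaN in ratio maps (outside quality support, non-finite
inputs, or NAA ≤ 1e-12); negative or non-finite linewidth marks an
undefined spectrum. The NAWM mean is the arithmetic mean over defined
voxels. No connected-component filtering or hole-filling is applied: in
clinical use such contours are edited by experts, and silent morphological
cleanup would diverge from the stated rule, so the raw threshold mask is
canonical. The NAWM ROI is user-supplied; automatic contralateral detection
is not attempted.

## Registration

The mid-treatment anatomy (pre-contrast T1) is registered to the
pre-treatment contrast-enhanced T1. Because the two have different
intensity profiles, the similarity metric is Mattes mutual information (32
bins, all voxels — no random sampling, so estimation is deterministic).
The rigid stage is an Euler transform initialized at the geometric centers
and optimized by regular-step gradient descent (learning rate 1.0, minimum
step 1e-4, ≤300 iterations, physical-shift scaling) over a 2-level
pyramid. An optional B-spline free-form stage (4×4×4 mesh, L-BFGS-B, ≤40
iterations) can follow, off by default — over a two-week interval rigid
alignment is usually sufficient. Similarity values are reported negated
(higher is better); a final value more than 1e-3 below the initial one is
treated as divergence and raised with the metric trace.

Propagation applies the one estimated transform to every member of the
moving scan: nearest neighbor for masks (the only choice that preserves
binarity), linear for anatomy and metabolite maps. NaN-coded undefined
voxels are preserved through linear resampling by transporting the
definedness mask with nearest neighbor and re-imposing NaN. A result must
be explicitly approved (after inspecting the written checkerboard-blend
snapshot) before it can be applied; identity transforms are exempt, and an
auto-approve flag exists for scripted runs. On synthetic phantoms, rigid
recovery of translations ≤ 10 mm is accurate to ≈0.1 mm, comfortably
within the 0.5 mm acceptance used in the tests.

## Harmonization

Linewidth filtering removes different voxels at the two timepoints, so
contours and maps are restricted to the intersection of the two quality
maps before comparison. When one quality map is nested in the other this is
exactly "apply the lower-coverage map to both"; for non-nested maps —
where that phrasing is ambiguous — the intersection is the only support on
which both maps are defined, and that is the convention adopted here.
Harmonization is idempotent, never grows a contour, and leaves overlap
statistics invariant to quality differences outside the union of the two
contours. Coverage fractions are reported relative to a brain mask when
supplied, else to the union of defined metabolite voxels. An empty common
support is an error (no comparable region); a contour fully occluded by the
other scan's dropout is legal but warned about.

## Overlap statistics

With voxel counts |A|, |B|, |A∩B| on the common grid: total overlap
|A∩B|/|B|, Jaccard |A∩B|/|A∪B|, Dice 2|A∩B|/(|A|+|B|), volume similarity
2(|A|−|B|)/(|A|+|B|) (range [−2, 2]), and signed volume change
(|B|−|A|)/|A| with growth positive and |ΔV| < 1e-9 reported as
"unchanged". The Hausdorff distance is computed between voxel centers in
world mm via an exact Euclidean distance transform sampled at the voxel
spacing; the default is the symmetric (max of both directed) form, with a
`directed` mode for the one-sided reading. Degenerate inputs follow fixed
conventions: both masks empty is an error (an empty pre/mid pair carries no
information and a conventional 1.0 would corrupt cohort medians); an empty
later mask yields total overlap 0 with a warning; an empty earlier mask
leaves the volume change undefined (missing).

Difference maps are `pre/norm_pre − mid/norm_mid` on the common support and
zero elsewhere, positive where Cho/NAA improved. Normalizers default to
each scan's mean NAWM ratio (falling back to 1.0) and are recorded in the
report; the normalization makes the map comparable across scans whose
absolute ratio scales differ.

Combined biomarkers are s·sign(ΔV) and s·ΔV (in percent) for
s ∈ {total overlap, Jaccard, Dice}, with sign(0) = 0.

## Survival screen

Kaplan–Meier estimation and the log-rank test are delegated to `lifelines`;
the screen itself — median stratification, the tie rule, the battery
bookkeeping — is this package's. Values equal to the median cutoff go to
the low group (a deterministic rule, flagged in the result when it makes
the split unequal beyond the odd-n imbalance). The log-rank test is
two-sided at α = 0.05. No multiple-testing correction is applied across
the battery; the number of tests performed is embedded in every result so
users can correct as they see fit. Stratification depends only on ranks,
so any strictly increasing transform of a biomarker yields identical
subgroups and p-values — which is why Dice and Jaccard, related by the
increasing map D = 2J/(1+J), always screen identically. A
growth-vs-reduction stratification (fixed cutoff at ΔV = 0) is screened as
an additional biomarker. Time origins are taken from the input table as
given (e.g. months from resection) and are not re-derived.

## Synthetic data

The generators define the conditions under which the pipeline is tested.

* **Mask pairs** are voxelized spheres: overlap statistics are
  shape-agnostic and spheres make ground truth analytic. Requested volumes
  are met within half a voxel by integer rounding. A target Jaccard J is
  achieved by fixing the intersection count to
  `round(J(|A|+|B|)/(1+J))` and growing the second mask deterministically
  from the intersection outward; the achievability bound
  `J_max = min(V)/max(V)` is validated analytically. The default spec
  reconstructs the reference case: 1.00 → 4.96 cc at 1 mm isotropic.
* **Metabolite phantoms** place a Cho/NAA lesion (default 2.0) over a
  normal background (default 0.5) with NAA ≡ 1, a mirrored contralateral
  NAWM ROI (~0.3 cc), a Gaussian head-like anatomy, and a linewidth map of
  10 Hz with a seeded random fraction (default 10%) raised to 25 Hz to
  emulate patchy quality dropout. By construction the 2×-NAWM threshold is
  twice the background, so the generated contour recovers the lesion
  exactly up to dropout.
* **Cohorts** draw a Gaussian biomarker (mean 0.37, sd 0.15 — centered on
  a realistic Dice scale) and exponential survival with median OS 15 months
  and median PFS 8 months in the low-risk group; subjects above the
  distribution mean form the true high-risk group whose hazard is
  multiplied by the specified hazard ratio. Censoring is an independent
  exponential calibrated to the requested expected censored fraction. All
  generators are bit-reproducible from their seed.

What the phantoms do **not** emulate: MR physics (no k-space, partial
volume, or noise correlations), realistic tumor morphology, anatomy-
dependent quality dropout, or registration failure modes from real
inter-scan deformation. Passing tests therefore demonstrate the
correctness of the computational contract — thresholding, resampling,
set arithmetic, distances, survival statistics — not clinical performance
on patient data.

## Problem sizes and numerical choices

Unit and acceptance tests run on grids of 24³–48³ voxels, 200 random mask
pairs up to 16³ for oracle comparison, 1000 replicates for log-rank null
calibration (two groups of 50), 200 replicates for power at hazard ratio 3
(n = 100), and a 27-patient synthetic cohort for end-to-end determinism —
sizes chosen so the full suite completes in a few minutes while keeping
Monte-Carlo error small relative to the tested bands. JSON/CSV outputs are
written with sorted keys and fixed float formatting so reruns are
byte-identical; reports embed the software version and a config hash.

## Known limitations

* The approval gate is a recorded boolean plus a snapshot path, not an
  interactive review tool.
* Interactive 3D rendering is replaced by a static marching-cubes OBJ
  export of the two contours.
* Only the linewidth criterion is implemented for spectral quality;
  upstream fitting-quality criteria must be baked into a supplied quality
  mask.
* No Cox modeling, covariate adjustment, or optimal-cutpoint search —
  median stratification only, by design.
* DICOM-RT structure sets are not parsed; masks must arrive rasterized.
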