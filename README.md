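# mrsipipe

Longitudinal spectroscopic-MRI change analysis for glioblastoma
radiotherapy: metabolic abnormality contouring, registration, coverage
harmonization, spatial overlap statistics, and survival-biomarker
screening.

## The problem

Glioblastoma infiltrates beyond what contrast-enhanced T1 and FLAIR MRI can
delineate, which makes radiation-therapy (RT) target definition uncertain.
Whole-brain spectroscopic MRI maps tumor metabolites voxel by voxel; the
choline-to-N-acetylaspartate ratio (Cho/NAA) is elevated in infiltrative
tumor and can define a metabolic target volume. When a patient is scanned
one week before RT (pre-RT) and again after two weeks of treatment
(mid-RT), the two abnormality volumes can be compared to ask two questions
that matter for adaptive RT planning:

1. **How much did the metabolic abnormality move or change?** Quantified by
   spatial overlap statistics between the two contours.
2. **Does that change predict outcome?** Tested by median-stratified
   Kaplan–Meier / log-rank screening against overall survival (OS) and
   progression-free survival (PFS).

`mrsipipe` implements this pipeline end to end for researchers working
with paired metabolite maps, plus a synthetic phantom/cohort generator so
every stage is testable without patient data.

## Method

**Contouring.** The abnormality volume is the set of spectra-quality voxels
with

&nbsp;&nbsp;&nbsp;&nbsp;Cho/NAA ≥ k · mean(Cho/NAA over contralateral NAWM),&nbsp;&nbsp;k = 2 by default,

where NAWM is a user-supplied normal-appearing-white-matter ROI. Voxels
with metabolite linewidth > 18 Hz are discarded as poor quality (18.0 Hz
exactly is retained).

**Registration and harmonization.** The mid-RT anatomy is rigidly
(optionally deformably) registered to the pre-RT anatomy with a mutual-
information metric; after explicit approval of the result the one transform
is propagated to every mid-RT map and mask (nearest neighbor for masks,
linear for intensities). Both scans are then restricted to the intersection
of their spectral-quality maps so overlap is measured on common support.

**Overlap statistics.** For binary contours A (pre-RT) and B (mid-RT):

| statistic | definition |
|---|---|
| total overlap | \|A∩B\| / \|B\| |
| Jaccard (union overlap) | \|A∩B\| / \|A∪B\| |
| Dice (mean overlap) | 2\|A∩B\| / (\|A\|+\|B\|) |
| volume similarity | 2(\|A\|−\|B\|) / (\|A\|+\|B\|) |
| Hausdorff distance | max nearest-point distance, world mm |
| volume change ΔV | (\|B\|−\|A\|) / \|A\|, growth positive |

Dice and Jaccard satisfy D = 2J/(1+J) identically. Combined biomarkers
multiply each overlap statistic by sign(ΔV) and by ΔV in percent.

**Survival screen.** For each biomarker the cohort is split at the sample
median, Kaplan–Meier curves are estimated per subgroup, and a two-sided
log-rank test (χ², 1 df) compares them for OS and PFS. Because the split
depends only on ranks, monotonically related biomarkers (Dice and Jaccard)
produce identical subgroups and p-values. No multiple-testing correction is
applied; the number of tests is reported.

## Worked example

Reconstruct the paired contours of the pipeline's reference case — a
1.00 cc pre-RT abnormality that grew to 4.96 cc at mid-RT — and compute
the overlap suite:

```python
from mrsipipe import PhantomSpec, make_mask_pair, overlap_report

a, b = make_mask_pair(PhantomSpec(lesion_volumes_cc=(1.00, 4.96),
                                  target_jaccard=0.063))
report = overlap_report(a, b)
print(round(report.jaccard, 3), round(report.dice, 3),
      round(report.volume_change_signed * 100, 1), report.direction)
```

prints

```
0.063 0.118 396.0 increase
```

i.e. a Jaccard coefficient of 0.063, a Dice coefficient of 0.118 (note
2·0.063/1.063 ≈ 0.118), and a +396% volume change: the abnormality nearly
quadrupled while barely overlapping its original position — exactly the
kind of case that motivates mid-course re-planning. The same pair through
the full pipeline (`run_pair`) additionally writes a JSON report, axial
overlay images, a signed Cho/NAA difference map (positive = improvement),
and an OBJ mesh scene of both contours.

The command-line interface exposes each stage (`mrsipipe contour`,
`register`, `harmonize`, `overlap`, `screen`, `simulate`, `run-pair`,
`run-cohort`); see `mrsipipe --help`.

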