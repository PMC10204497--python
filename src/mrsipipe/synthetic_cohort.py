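"""Synthetic phantoms and cohorts with known ground truth.

No study data are deposited with this pipeline, so every stage is exercised
on synthetic inputs: paired 3D binary masks with controllable volumes and
overlap, metabolite-ratio maps with an elevated-ratio lesion over a normal
background, patchy spectral-quality dropouts, and survival tables whose
hazard depends on a chosen imaging biomarker.

Lesions are voxelized spheres: overlap statistics are shape-agnostic, and
spheres make the ground truth analytic. Jaccard targeting works by fixing
the exact intersection count ``I = round(J (|A|+|B|) / (1+J))`` and growing
the later mask deterministically from the intersection outward, so the
achieved Jaccard is exact up to integer rounding. The achievability bound
is ``J_max = min(V_pre, V_mid) / max(V_pre, V_mid)``.

All generators are deterministic functions of their spec (including its
seed): identical specs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .contouring import linewidth_quality_mask
from .errors import PhantomSpecError
from .volume_model import BinaryMask, ScanRecord, VolumeGrid

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_mask_pair",
    "make_metabolite_phantom",
    "make_phantom_pair",
    "make_cohort",
]

LINEWIDTH_GOOD_HZ = 10.0
LINEWIDTH_BAD_HZ = 25.0


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a paired-lesion metabolite phantom.

    Defaults reconstruct the pipeline's worked example: a 1.00 cc
    pre-treatment abnormality growing to 4.96 cc at mid-treatment on a
    1 mm isotropic grid, with a Cho/NAA lesion at 2.0 over a 0.5 background
    (so the 2x-NAWM threshold is 1.0 by construction) and 10% patchy
    quality dropout.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_center: Optional[tuple[float, float, float]] = None
    lesion_volumes_cc: tuple[float, float] = (1.00, 4.96)
    target_jaccard: Optional[float] = None
    background_ratio: float = 0.5
    lesion_ratio: float = 2.0
    quality_dropout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise PhantomSpecError("spacing must be positive")
        if any(v <= 0 for v in self.lesion_volumes_cc):
            raise PhantomSpecError("lesion volumes must be positive")
        if not 0.0 <= self.quality_dropout_fraction <= 1.0:
            raise PhantomSpecError("quality_dropout_fraction must be in [0,1]")
        if self.target_jaccard is not None:
            if not 0.0 <= self.target_jaccard <= 1.0:
                raise PhantomSpecError("target_jaccard must be in [0,1]")
            va, vb = self.lesion_volumes_cc
            j_max = min(va, vb) / max(va, vb)
            if self.target_jaccard > j_max + 1e-9:
                raise PhantomSpecError(
                    f"target_jaccard {self.target_jaccard} unachievable for "
                    f"volumes {self.lesion_volumes_cc}: the maximum Jaccard of "
                    f"two masks with fixed volumes is min/max = {j_max:.4f}"
                )

    @property
    def center(self) -> np.ndarray:
        if self.lesion_center is not None:
            return np.asarray(self.lesion_center, dtype=float)
        # left-of-center so the mirrored NAWM ROI has room on the right
        return np.asarray(self.grid_shape, dtype=float) * (0.32, 0.5, 0.5)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic survival cohort.

    Survival is exponential: the low-biomarker group has median OS 15
    months and median PFS 8 months (glioblastoma-like); the true
    high-biomarker group's hazard is multiplied by ``hazard_ratio``.
    ``censoring_rate`` is the expected fraction censored, realized through
    an independent exponential censoring time.
    """

    n_patients: int = 27
    biomarker_mean: float = 0.37
    biomarker_sd: float = 0.15
    hazard_ratio: float = 1.0
    censoring_rate: float = 0.2
    median_os_low_months: float = 15.0
    median_pfs_low_months: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise PhantomSpecError("need at least 4 patients")
        if self.hazard_ratio <= 0:
            raise PhantomSpecError("hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise PhantomSpecError("censoring_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Mask-pair construction
# ---------------------------------------------------------------------------


def _world_distance_order(shape, spacing, point_idx) -> np.ndarray:
    """Flat voxel indices ordered by world-mm distance to a point (stable)."""
    idx = np.indices(shape).reshape(3, -1).T
    d = np.linalg.norm((idx - np.asarray(point_idx)) * np.asarray(spacing), axis=1)
    return np.argsort(d, kind="stable")


def _nearest_n(shape, spacing, point_idx, n, exclude: Optional[np.ndarray] = None
               ) -> np.ndarray:
    """Boolean mask of the n voxels nearest a point, optionally excluding some."""
    order = _world_distance_order(shape, spacing, point_idx)
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    if exclude is not None:
        order = order[~exclude.ravel()[order]]
    if n > order.size:
        raise PhantomSpecError(
            f"requested {n} voxels but only {order.size} available on the grid"
        )
    flat[order[:n]] = True
    return flat.reshape(shape)


def make_mask_pair(spec: PhantomSpec) -> tuple[BinaryMask, BinaryMask]:
    """Two lesion masks with requested volumes and (optionally) Jaccard.

    Volumes are matched to within half a voxel by integer rounding of the
    voxel counts. When ``target_jaccard`` is set, the intersection count is
    fixed analytically and the later mask grown outward from it, so the
    achieved Jaccard is within 0.01 of the target (exact up to rounding).
    """
    shape, spacing = spec.grid_shape, spec.spacing
    voxvol = float(np.prod(spacing))
    n_a = int(round(spec.lesion_volumes_cc[0] * 1000.0 / voxvol))
    n_b = int(round(spec.lesion_volumes_cc[1] * 1000.0 / voxvol))
    if n_a < 1 or n_b < 1:
        raise PhantomSpecError("requested volumes are below one voxel")
    center = spec.center
    a = _nearest_n(shape, spacing, center, n_a)
    r_a = (3.0 * n_a * voxvol / (4.0 * np.pi)) ** (1.0 / 3.0)  # equiv. radius mm
    growth_point = center + np.array([r_a, 0.0, 0.0]) / np.asarray(spacing)

    if spec.target_jaccard is None:
        b = _nearest_n(shape, spacing, growth_point, n_b)
    else:
        j = spec.target_jaccard
        n_i = int(round(j * (n_a + n_b) / (1.0 + j)))
        n_i = min(n_i, n_a, n_b)
        # intersection: the n_i voxels of A nearest the growth point
        order_a = _world_distance_order(shape, spacing, growth_point)
        in_a = a.ravel()
        inter_flat = order_a[in_a[order_a]][:n_i]
        inter = np.zeros(in_a.size, dtype=bool)
        inter[inter_flat] = True
        if n_i > 0:
            ref = np.mean(np.argwhere(inter.reshape(shape)), axis=0)
        else:
            ref = center + np.array([2.5 * r_a, 0.0, 0.0]) / np.asarray(spacing)
        extra = _nearest_n(shape, spacing, ref, n_b - n_i,
                           exclude=a) if n_b > n_i else np.zeros(shape, dtype=bool)
        b = inter.reshape(shape) | extra

    mask_a = BinaryMask(a, spacing)
    mask_b = BinaryMask(b, spacing)
    return mask_a, mask_b


# ---------------------------------------------------------------------------
# Metabolite phantoms
# ---------------------------------------------------------------------------


def _anatomy(shape, spacing, lesion) -> np.ndarray:
    """A smooth spherical head phantom with a bright lesion bump."""
    idx = np.indices(shape).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    r = np.sqrt(
        sum(((idx[i] - center[i]) * spacing[i]) ** 2 for i in range(3))
    )
    head_r = 0.45 * min(s * n for s, n in zip(spacing, shape))
    intensity = 100.0 * np.exp(-((r / head_r) ** 2))
    intensity[lesion] += 40.0
    return intensity


def _nawm_mask(spec: PhantomSpec, lesion: np.ndarray) -> np.ndarray:
    """Contralateral NAWM: mirror of the lesion center across the midline."""
    shape, spacing = spec.grid_shape, spec.spacing
    center = spec.center.copy()
    center[0] = (shape[0] - 1) - center[0]  # reflect across axis-0 midplane
    voxvol = float(np.prod(spacing))
    n = max(150, int(round(0.3 / voxvol)))  # ~0.3 cc reference ROI
    nawm = _nearest_n(shape, spacing, center, n, exclude=lesion)
    return nawm


def make_metabolite_phantom(spec: PhantomSpec, lesion: Optional[BinaryMask] = None,
                            timepoint_label: str = "other") -> ScanRecord:
    """A single-timepoint scan bundle whose contour ground truth is known.

    The Cho/NAA ratio is ``lesion_ratio`` inside the lesion and
    ``background_ratio`` elsewhere (NAA identically 1, Cho equal to the
    ratio), so the 2x-NAWM threshold equals twice the background and the
    generated contour recovers the lesion exactly up to quality dropouts.
    Dropout voxels get a linewidth above the 18 Hz cutoff, placed by the
    spec's seed.
    """
    if spec.lesion_ratio <= 2.0 * spec.background_ratio:
        raise PhantomSpecError(
            "lesion_ratio must exceed twice background_ratio for a detectable "
            "lesion under the 2x-NAWM rule"
        )
    shape, spacing = spec.grid_shape, spec.spacing
    if lesion is None:
        voxvol = float(np.prod(spacing))
        n = int(round(spec.lesion_volumes_cc[0] * 1000.0 / voxvol))
        lesion_data = _nearest_n(shape, spacing, spec.center, n)
    else:
        lesion_data = lesion.data

    ratio = np.full(shape, spec.background_ratio, dtype=float)
    ratio[lesion_data] = spec.lesion_ratio
    naa = np.ones(shape, dtype=float)
    cho = ratio * naa

    rng = np.random.default_rng(spec.seed)
    linewidth = np.full(shape, LINEWIDTH_GOOD_HZ, dtype=float)
    n_drop = int(round(spec.quality_dropout_fraction * linewidth.size))
    if n_drop:
        drop = rng.choice(linewidth.size, size=n_drop, replace=False)
        linewidth.ravel()[drop] = LINEWIDTH_BAD_HZ

    lw_grid = VolumeGrid(linewidth, spacing)
    quality = linewidth_quality_mask(lw_grid)
    return ScanRecord(
        anatomy=VolumeGrid(_anatomy(shape, spacing, lesion_data), spacing),
        quality=quality,
        cho=VolumeGrid(cho, spacing),
        naa=VolumeGrid(naa, spacing),
        ratio=VolumeGrid(ratio, spacing),
        linewidth=lw_grid,
        nawm=BinaryMask(_nawm_mask(spec, lesion_data), spacing),
        timepoint_label=timepoint_label,
    )


def make_phantom_pair(spec: PhantomSpec) -> tuple[ScanRecord, ScanRecord]:
    """Pre-/mid-treatment phantoms sharing a grid, with paired lesions.

    The two lesions have the spec's volumes (and target Jaccard, if set);
    each timepoint gets an independent dropout pattern derived from the
    spec seed.
    """
    lesion_pre, lesion_mid = make_mask_pair(spec)
    from dataclasses import replace as _replace
    pre = make_metabolite_phantom(_replace(spec, seed=spec.seed * 2 + 1),
                                  lesion=lesion_pre, timepoint_label="pre_RT")
    mid = make_metabolite_phantom(_replace(spec, seed=spec.seed * 2 + 2),
                                  lesion=lesion_mid, timepoint_label="mid_RT")
    return pre, mid


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """A synthetic cohort whose hazard depends on the true biomarker group.

    The biomarker is Gaussian; subjects above the distribution median
    (the mean, for a Gaussian) form the true high-risk group whose OS and
    PFS hazards are multiplied by ``hazard_ratio``. Censoring is an
    independent exponential calibrated so the expected censored fraction is
    ``censoring_rate``. Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    biomarker = rng.normal(spec.biomarker_mean, spec.biomarker_sd, size=n)
    high = biomarker > spec.biomarker_mean

    rows = {"patient_id": [f"P{i:03d}" for i in range(n)],
            "biomarker": biomarker, "true_group": np.where(high, "high", "low")}
    for label, med in (("os", spec.median_os_low_months),
                       ("pfs", spec.median_pfs_low_months)):
        lam = np.log(2.0) / med * np.where(high, spec.hazard_ratio, 1.0)
        event_t = rng.exponential(1.0 / lam)
        if spec.censoring_rate > 0:
            lam_c = spec.censoring_rate / (1.0 - spec.censoring_rate) * lam
            censor_t = rng.exponential(1.0 / lam_c)
        else:
            censor_t = np.full(n, np.inf)
        rows[f"{label}_months"] = np.minimum(event_t, censor_t)
        rows[f"{label}_event"] = event_t <= censor_t
    return pd.DataFrame(rows)
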