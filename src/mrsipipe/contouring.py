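"""Metabolic-abnormality contouring from Cho/NAA maps.

The choline-to-N-acetylaspartate (Cho/NAA) ratio is elevated in infiltrative
tumor. The abnormality contour is the set of voxels whose ratio is at least
``k`` times (default twice) the mean ratio in a contralateral
normal-appearing-white-matter (NAWM) reference ROI, restricted to voxels of
adequate spectral quality. Spectral quality is judged by metabolite
linewidth: voxels whose linewidth exceeds 18 Hz are discarded as
poor-quality; the cutoff itself (18.0 Hz exactly) is retained.

Undefined voxels in ratio maps are encoded as NaN; in linewidth maps any
negative or non-finite value marks an undefined voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContouringError
from .volume_model import BinaryMask, VolumeGrid, assert_same_grid

__all__ = [
    "ContourParams",
    "linewidth_quality_mask",
    "ratio_map",
    "nawm_threshold",
    "generate_abnormality_contour",
    "contour_scan",
]

#: Denominator floor below which the ratio at a voxel is declared undefined.
NAA_EPSILON = 1e-12


@dataclass(frozen=True)
class ContourParams:
    """Tunable parameters of the contouring rule.

    ratio_multiplier
        The factor k applied to the mean NAWM Cho/NAA; the canonical
        abnormality volume uses k = 2 ("Cho/NAA >= 2x").
    linewidth_cutoff_hz
        Spectral linewidth above which a voxel is removed (Hz).
    min_nawm_voxels
        Minimum NAWM voxels inside the defined ratio support; below this
        the threshold is deemed unstable.
    """

    ratio_multiplier: float = 2.0
    linewidth_cutoff_hz: float = 18.0
    min_nawm_voxels: int = 50

    def __post_init__(self) -> None:
        if self.ratio_multiplier <= 0:
            raise ValueError("ratio_multiplier must be > 0")
        if self.linewidth_cutoff_hz <= 0:
            raise ValueError("linewidth_cutoff_hz must be > 0")
        if self.min_nawm_voxels < 1:
            raise ValueError("min_nawm_voxels must be >= 1")


def linewidth_quality_mask(linewidth: VolumeGrid, cutoff_hz: float = 18.0) -> BinaryMask:
    """Binary quality map: voxels defined and with linewidth <= cutoff.

    Removal is strict ("greater than cutoff removed"), so a voxel at exactly
    the cutoff is retained. Undefined voxels (negative or non-finite
    linewidth) are never retained. An all-removed map yields an empty mask
    with a warning rather than an error.
    """
    lw = np.asarray(linewidth.data, dtype=float)
    defined = np.isfinite(lw) & (lw >= 0)
    mask = defined & (lw <= cutoff_hz)
    if not mask.any():
        warnings.warn(
            "linewidth filtering removed every voxel; quality mask is empty",
            stacklevel=2,
        )
    return BinaryMask(mask, linewidth.spacing, linewidth.origin, linewidth.direction)


def ratio_map(cho: VolumeGrid, naa: VolumeGrid, quality: BinaryMask) -> VolumeGrid:
    """Voxelwise Cho/NAA inside the quality support; NaN where undefined.

    A voxel is undefined when it lies outside the quality support, either
    metabolite value is non-finite, or NAA is at or below a small epsilon
    (degenerate denominator).
    """
    assert_same_grid([cho, naa, quality])
    c = np.asarray(cho.data, dtype=float)
    n = np.asarray(naa.data, dtype=float)
    valid = quality.data & np.isfinite(c) & np.isfinite(n) & (n > NAA_EPSILON)
    out = np.full(c.shape, np.nan)
    out[valid] = c[valid] / n[valid]
    return cho.with_data(out)


def nawm_threshold(ratio: VolumeGrid, nawm: BinaryMask, k: float = 2.0,
                   min_nawm_voxels: int = 50) -> float:
    """Abnormality threshold: k times the mean ratio over the NAWM ROI.

    The mean is the arithmetic mean of defined ratio voxels inside the
    NAWM mask. Raises :class:`ContouringError` when fewer than
    ``min_nawm_voxels`` NAWM voxels carry a defined ratio, since a mean over
    a handful of voxels makes the threshold unstable.
    """
    assert_same_grid([ratio, nawm])
    sel = nawm.data & np.isfinite(ratio.data)
    n_sel = int(np.count_nonzero(sel))
    if n_sel < min_nawm_voxels:
        raise ContouringError(
            f"only {n_sel} NAWM voxels inside the defined ratio support "
            f"(need >= {min_nawm_voxels}); threshold would be unstable"
        )
    return float(k * np.mean(ratio.data[sel]))


def generate_abnormality_contour(ratio: VolumeGrid, threshold: float,
                                 quality: BinaryMask) -> BinaryMask:
    """Mask of voxels with defined ratio >= threshold inside quality support.

    The boundary is inclusive and no morphological post-processing is
    applied: the raw threshold mask is canonical. An empty result is legal
    (the abnormality may lie entirely in a quality dropout).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    assert_same_grid([ratio, quality])
    with np.errstate(invalid="ignore"):
        sel = np.isfinite(ratio.data) & quality.data & (ratio.data >= threshold)
    return BinaryMask(sel, ratio.spacing, ratio.origin, ratio.direction)


def contour_scan(scan, params: ContourParams = ContourParams()) -> BinaryMask:
    """Run the full contouring rule on a :class:`ScanRecord`.

    Builds the ratio map from cho/naa if a precomputed one is absent, derives
    the NAWM-based threshold, and returns the abnormality contour.
    """
    if not scan.has_ratio_source():
        raise ContouringError("scan carries neither a ratio map nor cho+naa maps")
    if scan.nawm is None:
        raise ContouringError("contouring requires a NAWM reference ROI")
    if scan.ratio is not None:
        ratio = scan.ratio.with_data(
            np.where(scan.quality.data, scan.ratio.data, np.nan)
        )
    else:
        ratio = ratio_map(scan.cho, scan.naa, scan.quality)
    thr = nawm_threshold(ratio, scan.nawm, params.ratio_multiplier,
                         params.min_nawm_voxels)
    return generate_abnormality_contour(ratio, thr, scan.quality)
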