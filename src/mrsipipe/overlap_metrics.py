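"""Spatial overlap statistics, volume change, and difference maps.

For binary contours A (earlier scan) and B (later scan) on one grid, the
suite comprises:

* total overlap   |A∩B| / |B|
* Jaccard         |A∩B| / |A∪B|        ("union overlap")
* Dice            2|A∩B| / (|A|+|B|)   ("mean overlap")
* volume similarity  2(|A|−|B|) / (|A|+|B|), range [−2, 2]
* Hausdorff distance in world mm (symmetric by default)
* signed volume change  ΔV = (|B|−|A|) / |A|, growth positive

Dice and Jaccard obey D = 2J/(1+J) identically. Distances are computed
between voxel centers in world coordinates so anisotropic spacing is
honored. Combined biomarkers multiply each overlap statistic by the
direction (sign) and by the percentage of volume change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import UndefinedMetricError
from .volume_model import BinaryMask, VolumeGrid, assert_same_grid

__all__ = [
    "OverlapReport",
    "DifferenceMap",
    "overlap_report",
    "hausdorff_mm",
    "difference_map",
    "combined_biomarkers",
]

#: |ΔV| below this is reported as direction "unchanged".
VOLUME_CHANGE_TIE_TOL = 1e-9


@dataclass
class OverlapReport:
    """The full overlap-statistic set for one registered, harmonized pair."""

    vol_a_cc: float
    vol_b_cc: float
    intersection_cc: float
    union_cc: float
    total_overlap: float
    jaccard: float
    dice: float
    volume_similarity: float
    hausdorff_mm: float
    volume_change_signed: Optional[float]
    volume_change_abs: Optional[float]
    direction: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DifferenceMap:
    """Signed change map on the common support.

    Positive values mark improvement (Cho/NAA decreased from pre to mid),
    negative values new or worsening abnormality. Zero outside support.
    """

    data: np.ndarray
    support: BinaryMask
    normalizer_pre: float
    normalizer_mid: float


def _counts(a: BinaryMask, b: BinaryMask) -> tuple[int, int, int]:
    na = int(np.count_nonzero(a.data))
    nb = int(np.count_nonzero(b.data))
    ni = int(np.count_nonzero(a.data & b.data))
    return na, nb, ni


def overlap_report(a: BinaryMask, b: BinaryMask,
                   hausdorff_mode: str = "symmetric") -> OverlapReport:
    """Compute the overlap-statistic suite for masks A (earlier) and B (later).

    Raises :class:`UndefinedMetricError` when both masks are empty: an empty
    pre/mid pair carries no information, and conventionally reporting
    perfect overlap would corrupt cohort medians. An empty B yields total
    overlap 0 with a warning; an empty A leaves the volume change undefined
    (reported as missing).
    """
    assert_same_grid([a, b])
    na, nb, ni = _counts(a, b)
    if na == 0 and nb == 0:
        raise UndefinedMetricError("both masks are empty; overlap is undefined")
    nu = na + nb - ni
    vv = a.voxel_volume_mm3 / 1000.0  # cc per voxel

    if nb == 0:
        warnings.warn("later-scan mask B is empty; total overlap reported as 0",
                      stacklevel=2)
        total = 0.0
    else:
        total = ni / nb
    jaccard = ni / nu
    dice = 2.0 * ni / (na + nb)
    vs = 2.0 * (na - nb) / (na + nb)

    if na == 0:
        dv: Optional[float] = None
        dv_abs: Optional[float] = None
        direction = "unchanged" if nb == 0 else "increase"
    else:
        dv = (nb - na) / na
        dv_abs = abs(dv)
        if dv_abs < VOLUME_CHANGE_TIE_TOL:
            direction = "unchanged"
        else:
            direction = "increase" if dv > 0 else "decrease"

    hd = hausdorff_mm(a, b, hausdorff_mode) if (na and nb) else math.inf

    return OverlapReport(
        vol_a_cc=na * vv,
        vol_b_cc=nb * vv,
        intersection_cc=ni * vv,
        union_cc=nu * vv,
        total_overlap=total,
        jaccard=jaccard,
        dice=dice,
        volume_similarity=vs,
        hausdorff_mm=hd,
        volume_change_signed=dv,
        volume_change_abs=dv_abs,
        direction=direction,
    )


def hausdorff_mm(a: BinaryMask, b: BinaryMask, mode: str = "symmetric") -> float:
    """Hausdorff distance between voxel-center sets, in world mm.

    ``directed`` is the maximum over voxels of A of the distance to the
    nearest voxel of B; ``symmetric`` (default) is the maximum of the two
    directed values. Computed with an exact Euclidean distance transform
    whose sampling equals the voxel spacing, so anisotropic grids give
    physical distances.
    """
    if mode not in ("directed", "symmetric"):
        raise ValueError(f"unknown Hausdorff mode {mode!r}")
    assert_same_grid([a, b])
    if not a.data.any() or not b.data.any():
        raise UndefinedMetricError("Hausdorff distance needs two nonempty masks")

    def directed(src: BinaryMask, dst: BinaryMask) -> float:
        dt = ndimage.distance_transform_edt(~dst.data, sampling=src.spacing)
        return float(dt[src.data].max())

    d_ab = directed(a, b)
    if mode == "directed":
        return d_ab
    return max(d_ab, directed(b, a))


def difference_map(ratio_pre: VolumeGrid, ratio_mid: VolumeGrid,
                   support: BinaryMask,
                   normalizer_pre: float = 1.0,
                   normalizer_mid: float = 1.0) -> DifferenceMap:
    """Normalized pre-minus-mid ratio difference on the common support.

    ``data = ratio_pre/normalizer_pre − ratio_mid/normalizer_mid`` where both
    are defined inside the support, zero elsewhere; positive where the
    Cho/NAA ratio improved (decreased) between scans. Antisymmetric under
    swapping the two inputs (with their normalizers).
    """
    if normalizer_pre <= 0 or normalizer_mid <= 0:
        raise ValueError("normalizers must be positive")
    assert_same_grid([ratio_pre, ratio_mid, support])
    pre = np.asarray(ratio_pre.data, dtype=float)
    mid = np.asarray(ratio_mid.data, dtype=float)
    valid = support.data & np.isfinite(pre) & np.isfinite(mid)
    out = np.zeros(pre.shape)
    out[valid] = pre[valid] / normalizer_pre - mid[valid] / normalizer_mid
    return DifferenceMap(out, support, float(normalizer_pre), float(normalizer_mid))


def combined_biomarkers(report: OverlapReport) -> list[tuple[str, Optional[float]]]:
    """Products of each overlap statistic with direction and % volume change.

    For each base statistic s in {total_overlap, jaccard, dice} emits
    ``s × sign(ΔV)`` and ``s × ΔV`` expressed as a percentage, with
    sign(0) = 0. When the volume change is undefined (empty earlier mask)
    the combined values are missing (None).
    """
    dv = report.volume_change_signed
    if dv is None:
        sign: Optional[float] = None
    elif abs(dv) < VOLUME_CHANGE_TIE_TOL:
        sign = 0.0
    else:
        sign = math.copysign(1.0, dv)
    out: list[tuple[str, Optional[float]]] = []
    for name in ("total_overlap", "jaccard", "dice"):
        s = getattr(report, name)
        if sign is None:
            out.append((f"{name}_x_direction", None))
            out.append((f"{name}_x_change_pct", None))
        else:
            out.append((f"{name}_x_direction", s * sign))
            out.append((f"{name}_x_change_pct", s * dv * 100.0))
    return out
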