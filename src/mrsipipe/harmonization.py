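"""Common spectral-quality support for a registered scan pair.

Linewidth filtering removes different voxels at the two timepoints, so the
two metabolite maps (and the contours derived from them) are defined on
different supports. To compare like with like, both scans are restricted to
the intersection of their quality maps before any overlap statistic is
computed. When one quality map is nested in the other this reduces exactly
to applying the lower-coverage map to both scans; the intersection also
covers the non-nested case, where "lower coverage" alone is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import HarmonizationError
from .volume_model import BinaryMask, ScanRecord, assert_same_grid

__all__ = ["HarmonizedPair", "harmonize"]


@dataclass
class HarmonizedPair:
    """A scan pair restricted to common quality support.

    ``pre``/``mid`` are the harmonized records; the originals are preserved
    alongside as ``pre_raw``/``mid_raw``. Coverage fractions are relative to
    a brain mask when one is supplied, else to the union of voxels where
    either scan's metabolite data are defined.
    """

    pre: ScanRecord
    mid: ScanRecord
    common_support: BinaryMask
    pre_raw: ScanRecord
    mid_raw: ScanRecord
    coverage_pre: float
    coverage_mid: float
    coverage_common: float


def _restrict(scan: ScanRecord, support: BinaryMask) -> ScanRecord:
    """Zero/undefine every member outside the support; quality := support."""
    kwargs: dict = {"quality": support}
    for name in ("ratio", "cho", "naa", "linewidth"):
        vol = getattr(scan, name)
        if vol is not None:
            data = np.asarray(vol.data, dtype=float).copy()
            data[~support.data] = np.nan
            kwargs[name] = vol.with_data(data)
    if scan.contour is not None:
        kwargs["contour"] = scan.contour.with_data(scan.contour.data & support.data)
    return replace(scan, **kwargs)


def harmonize(pre: ScanRecord, mid: ScanRecord,
              brain_mask: Optional[BinaryMask] = None) -> HarmonizedPair:
    """Impose the intersection of the two quality maps on both scans.

    Both contours are intersected with the common support and both ratio
    maps masked to it. Raises :class:`HarmonizationError` when the common
    support is empty (no comparable region). Warns when harmonization
    empties a previously nonempty contour (total occlusion by the other
    scan's quality dropout).
    """
    assert_same_grid(list(pre.volumes()) + list(mid.volumes()))
    common = pre.quality.with_data(pre.quality.data & mid.quality.data)
    if not common.data.any():
        raise HarmonizationError(
            "quality maps have empty intersection; no comparable region"
        )

    if brain_mask is not None:
        ref = brain_mask.data
    else:
        ref = _defined_union(pre) | _defined_union(mid)
    n_ref = max(int(np.count_nonzero(ref)), 1)

    pair = HarmonizedPair(
        pre=_restrict(pre, common),
        mid=_restrict(mid, common),
        common_support=common,
        pre_raw=pre,
        mid_raw=mid,
        coverage_pre=int(np.count_nonzero(pre.quality.data & ref)) / n_ref,
        coverage_mid=int(np.count_nonzero(mid.quality.data & ref)) / n_ref,
        coverage_common=int(np.count_nonzero(common.data & ref)) / n_ref,
    )
    for label, raw, harm in (("pre", pre, pair.pre), ("mid", mid, pair.mid)):
        if raw.contour is not None and raw.contour.data.any() \
                and not harm.contour.data.any():
            warnings.warn(
                f"{label} contour lies entirely outside the common quality "
                "support; harmonized contour is empty",
                stacklevel=2,
            )
    return pair


def _defined_union(scan: ScanRecord) -> np.ndarray:
    """Voxels where any metabolite map of the scan is defined."""
    out = np.zeros(scan.anatomy.shape, dtype=bool)
    for name in ("ratio", "cho", "naa"):
        vol = getattr(scan, name)
        if vol is not None:
            out |= np.isfinite(np.asarray(vol.data, dtype=float))
    if not out.any():
        out |= scan.quality.data
    return out
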