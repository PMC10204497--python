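"""Rigid (optionally plus deformable) registration and transform propagation.

The mid-treatment anatomy is registered to the pre-treatment anatomy; once
the result is explicitly approved, the same transform is propagated to every
other volume of the mid-treatment scan (contours and metabolite maps), which
are resampled onto the pre-treatment grid. Because the pre-treatment
anatomy is contrast-enhanced while the mid-treatment one is not, the
similarity metric is Mattes mutual information, which tolerates differing
intensity profiles; similarity values reported here are the negated metric,
so larger means better aligned.

Interpolation is fixed by data role: nearest neighbor for masks (preserving
binarity exactly), linear for anatomy and metabolite maps. NaN-coded
undefined voxels in ratio maps are handled by resampling their definedness
mask alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import SimpleITK as sitk

from .errors import ApprovalRequiredError, RegistrationError
from .volume_model import BinaryMask, ScanRecord, VolumeGrid

__all__ = [
    "SpatialTransform",
    "RegistrationResult",
    "estimate_transform",
    "apply_transform",
    "propagate",
    "identity_result",
    "save_transform",
    "load_transform",
]

#: Allowed worsening of the similarity metric before declaring divergence.
DIVERGENCE_TOL = 1e-3


@dataclass
class SpatialTransform:
    """A spatial mapping plus the fixed grid the output is resampled onto."""

    kind: str  # {rigid, deformable, composite, identity}
    sitk_transform: sitk.Transform
    fixed_grid: VolumeGrid

    def __post_init__(self) -> None:
        if self.kind not in ("rigid", "deformable", "composite", "identity"):
            raise ValueError(f"unknown transform kind {self.kind!r}")


@dataclass
class RegistrationResult:
    """Outcome of transform estimation, gated on explicit approval.

    ``approved`` defaults to False and must be set by an explicit call to
    :meth:`approve` (or an auto-approve flag in scripted runs) before the
    transform may be propagated.
    """

    transform: SpatialTransform
    similarity_before: float
    similarity_after: float
    approved: bool = False
    blend_snapshot: Optional[str] = None
    metric_trace: list = field(default_factory=list)

    def approve(self) -> "RegistrationResult":
        self.approved = True
        return self


def rigid_component(transform: sitk.Transform) -> sitk.Euler3DTransform:
    """Extract the rigid (Euler) stage from a possibly composite transform."""
    candidates = [transform]
    if isinstance(transform, sitk.CompositeTransform) or \
            transform.GetName() == "CompositeTransform":
        comp = sitk.CompositeTransform(transform)
        candidates = [comp.GetNthTransform(i)
                      for i in range(comp.GetNumberOfTransforms())]
    for cand in candidates:
        try:
            return sitk.Euler3DTransform(cand)
        except RuntimeError:
            continue
    raise ValueError("transform carries no rigid (Euler3D) component")


def identity_result(fixed_grid: VolumeGrid) -> RegistrationResult:
    """An identity transform result (already co-registered inputs).

    Identity transforms are exempt from the approval gate: they map every
    world point to itself.
    """
    tfm = SpatialTransform("identity", sitk.Transform(3, sitk.sitkIdentity),
                           fixed_grid)
    return RegistrationResult(tfm, 0.0, 0.0, approved=True)


def _mattes_similarity(fixed: sitk.Image, moving: sitk.Image,
                       transform: sitk.Transform) -> float:
    r = sitk.ImageRegistrationMethod()
    r.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    r.SetInterpolator(sitk.sitkLinear)
    r.SetInitialTransform(transform, inPlace=False)
    return -float(r.MetricEvaluate(fixed, moving))


def estimate_transform(fixed: VolumeGrid, moving: VolumeGrid,
                       mode: str = "rigid",
                       snapshot_path: Optional[str] = None) -> RegistrationResult:
    """Estimate a rigid (optionally followed by B-spline) transform.

    The returned result is *not* approved; a checkerboard-blend snapshot of
    the aligned pair is written to ``snapshot_path`` (if given) for the
    visual check that precedes approval.
    """
    if mode not in ("rigid", "rigid_then_deformable"):
        raise ValueError(f"unknown registration mode {mode!r}")
    for name, vol in (("fixed", fixed), ("moving", moving)):
        if float(np.nanstd(np.asarray(vol.data, dtype=float))) == 0.0:
            raise RegistrationError(
                f"{name} volume has zero intensity variance; nothing to align"
            )

    fimg = fixed.to_sitk(np.float32)
    mimg = moving.to_sitk(np.float32)

    initial = sitk.CenteredTransformInitializer(
        fimg, mimg, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    sim_before = _mattes_similarity(fimg, mimg, sitk.Transform(3, sitk.sitkIdentity))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=300,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(initial, inPlace=False)
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    trace: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent,
                   lambda: trace.append(-float(reg.GetMetricValue())))
    try:
        rigid = reg.Execute(fimg, mimg)
    except RuntimeError as exc:
        raise RegistrationError(f"optimizer failed: {exc}; trace={trace}") from exc

    transform: sitk.Transform = rigid
    kind = "rigid"
    if mode == "rigid_then_deformable":
        transform, trace = _deformable_stage(fimg, mimg, rigid, trace)
        kind = "composite"

    sim_after = _mattes_similarity(fimg, mimg, transform)
    if sim_after < sim_before - DIVERGENCE_TOL:
        raise RegistrationError(
            f"registration diverged: similarity {sim_before:.5f} -> "
            f"{sim_after:.5f}; trace={trace}"
        )

    result = RegistrationResult(
        SpatialTransform(kind, transform, fixed),
        similarity_before=sim_before,
        similarity_after=sim_after,
        metric_trace=trace,
    )
    if snapshot_path is not None:
        result.blend_snapshot = str(snapshot_path)
        _write_blend_snapshot(fixed, moving, result, snapshot_path)
    return result


def _deformable_stage(fimg, mimg, rigid, trace):
    """B-spline free-form deformation refined on top of the rigid stage."""
    mesh = [4, 4, 4]
    bspline = sitk.BSplineTransformInitializer(fimg, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-5,
                             numberOfIterations=40)
    reg.SetMovingInitialTransform(rigid)
    reg.SetInitialTransform(bspline, inPlace=True)
    try:
        reg.Execute(fimg, mimg)
    except RuntimeError as exc:
        raise RegistrationError(f"deformable stage failed: {exc}") from exc
    composite = sitk.CompositeTransform(3)
    composite.AddTransform(rigid)     # applied first
    composite.AddTransform(bspline)   # refinement on top
    return composite, trace


def _write_blend_snapshot(fixed: VolumeGrid, moving: VolumeGrid,
                          result: RegistrationResult, path) -> None:
    """Save a checkerboard blend of the central axial slice as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    resampled = _resample(moving, result.transform, sitk.sitkLinear)

    def norm(sl):
        lo, hi = np.nanpercentile(sl, [1, 99])
        return np.clip((sl - lo) / (hi - lo + 1e-12), 0, 1)

    k = fixed.shape[2] // 2
    f_sl = norm(np.asarray(fixed.data[:, :, k], dtype=float))
    m_sl = norm(np.asarray(resampled.data[:, :, k], dtype=float))
    tiles = 8
    ii, jj = np.indices(f_sl.shape)
    ti = (ii // max(1, f_sl.shape[0] // tiles) + jj // max(1, f_sl.shape[1] // tiles))
    board = np.where(ti % 2 == 0, f_sl, m_sl)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(board.T, cmap="gray", origin="lower")
    ax.set_title("checkerboard blend (fixed/moving)")
    ax.axis("off")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def _resample(volume: VolumeGrid, transform: SpatialTransform,
              interp) -> VolumeGrid:
    is_mask = volume.data.dtype == bool
    img = volume.to_sitk(np.uint8 if is_mask else np.float64)
    fg = transform.fixed_grid
    ref = VolumeGrid(np.zeros(fg.shape, dtype=np.uint8), fg.spacing,
                     fg.origin, fg.direction).to_sitk()
    out = sitk.Resample(img, ref, transform.sitk_transform, interp, 0.0,
                        img.GetPixelID())
    grid = VolumeGrid.from_sitk(out)
    if is_mask:
        return BinaryMask(grid.data > 0, grid.spacing, grid.origin, grid.direction)
    return grid


def apply_transform(volume: VolumeGrid, result: RegistrationResult,
                    interpolation: str = "linear") -> VolumeGrid:
    """Resample a volume onto the fixed grid through an approved transform.

    Nearest interpolation preserves the input's value set exactly; identity
    transforms are exempt from the approval gate.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if result.transform.kind != "identity" and not result.approved:
        raise ApprovalRequiredError(
            "registration result has not been approved; call .approve() "
            "after the visual check (or use auto-approve in scripted runs)"
        )
    interp = sitk.sitkNearestNeighbor if interpolation == "nearest" else sitk.sitkLinear
    data = np.asarray(volume.data)
    if interpolation == "linear" and np.issubdtype(data.dtype, np.floating) \
            and np.isnan(data).any():
        # Resample the definedness mask with nearest neighbor and re-impose
        # NaN where the source voxel was undefined.
        defined = BinaryMask(np.isfinite(data), volume.spacing, volume.origin,
                             volume.direction)
        filled = volume.with_data(np.nan_to_num(data, nan=0.0))
        out = _resample(filled, result.transform, interp)
        dmask = _resample(defined, result.transform, sitk.sitkNearestNeighbor)
        vals = out.data.copy()
        vals[~dmask.data] = np.nan
        return out.with_data(vals)
    return _resample(volume, result.transform, interp)


def propagate(scan: ScanRecord, result: RegistrationResult) -> ScanRecord:
    """Resample every member of a scan with the one approved transform.

    Masks and quality maps use nearest-neighbor interpolation; anatomy and
    metabolite maps use linear. The output record lives on the fixed
    (pre-treatment) grid.
    """
    if result.transform.kind != "identity" and not result.approved:
        raise ApprovalRequiredError("cannot propagate an unapproved registration")
    kwargs = {}
    for name, vol in scan.members():
        interp = "nearest" if isinstance(vol, BinaryMask) else "linear"
        kwargs[name] = apply_transform(vol, result, interp)
    return replace(scan, **kwargs)


# ---------------------------------------------------------------------------
# Transform serialization (rigid/identity as JSON; others via SimpleITK files)
# ---------------------------------------------------------------------------


def save_transform(result: RegistrationResult, path) -> None:
    path = Path(path)
    tfm = result.transform
    doc = {
        "kind": tfm.kind,
        "approved": result.approved,
        "similarity_before": result.similarity_before,
        "similarity_after": result.similarity_after,
        "fixed_grid": {
            "shape": list(tfm.fixed_grid.shape),
            "spacing": list(tfm.fixed_grid.spacing),
            "origin": list(tfm.fixed_grid.origin),
            "direction": tfm.fixed_grid.direction.flatten().tolist(),
        },
    }
    if tfm.kind == "rigid":
        euler = rigid_component(tfm.sitk_transform)
        doc["parameters"] = list(euler.GetParameters())
        doc["fixed_parameters"] = list(euler.GetFixedParameters())
    elif tfm.kind != "identity":
        sidecar = path.with_suffix(".tfm")
        sitk.WriteTransform(tfm.sitk_transform, str(sidecar))
        doc["transform_file"] = sidecar.name
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_transform(path) -> RegistrationResult:
    path = Path(path)
    doc = json.loads(path.read_text())
    g = doc["fixed_grid"]
    fixed_grid = VolumeGrid(
        np.zeros(tuple(g["shape"]), dtype=np.uint8),
        tuple(g["spacing"]), tuple(g["origin"]),
        np.asarray(g["direction"]).reshape(3, 3),
    )
    kind = doc["kind"]
    if kind == "identity":
        tfm: sitk.Transform = sitk.Transform(3, sitk.sitkIdentity)
    elif kind == "rigid":
        euler = sitk.Euler3DTransform()
        euler.SetFixedParameters(doc["fixed_parameters"])
        euler.SetParameters(doc["parameters"])
        tfm = euler
    else:
        tfm = sitk.ReadTransform(str(path.parent / doc["transform_file"]))
    result = RegistrationResult(
        SpatialTransform(kind, tfm, fixed_grid),
        doc["similarity_before"], doc["similarity_after"],
        approved=bool(doc["approved"]),
    )
    return result
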