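"""Rigid volume-to-volume registration (CT -> CBCT, MRI -> CBCT).

The bone-to-bone CT-to-CBCT link is: rough intensity-window bone masking,
rigid initialization by aligning the centers of mass of the two bone masks,
then mutual-information registration restricted to the masked voxels.  The
preoperative-MRI link is a rigid registration restricted to a region of
interest around the target lesion; clinically that alignment was performed
manually, so a verbatim "manual mode" pass-through is provided alongside the
automated surrogate used in tests.

The optimization itself runs on ITK's registration framework (SimpleITK):
Mattes mutual information on a fixed full sampling grid (no random
sampling), linear interpolation, multi-resolution, regular-step gradient
descent — deterministic for identical inputs and parameters (enforced
single-threaded so floating-point reduction order is fixed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ConfigError, EmptyMaskError, FrameError
from .geometry import RigidTransform
from .volume import VolumeImage

log = logging.getLogger(__name__)


@dataclass
class RegistrationParams:
    bone_lo: float = 600.0
    bone_hi: float = 1600.0
    bins: int = 64
    shrink_factors: tuple = (4, 2, 1)
    smoothing_sigmas: tuple = (4.0, 2.0, 1.0)
    mask_dilation: int = 3
    learning_rate: float = 2.0
    min_step: float = 1e-4
    max_iterations: int = 200
    relaxation_factor: float = 0.6

    def __post_init__(self):
        if self.bone_lo >= self.bone_hi:
            raise ConfigError(f"bone window lo {self.bone_lo} must be < hi {self.bone_hi}")
        if self.bins < 8:
            raise ConfigError(f"need >= 8 histogram bins, got {self.bins}")
        if len(self.shrink_factors) < 1:
            raise ConfigError("need >= 1 multi-resolution level")
        if len(self.smoothing_sigmas) != len(self.shrink_factors):
            raise ConfigError("smoothing_sigmas must match shrink_factors in length")


@dataclass(frozen=True)
class MIResult:
    transform: RigidTransform  # moving frame -> fixed frame
    metric: float  # final Mattes metric (negative mutual information)
    converged: bool
    iterations: int
    stop_condition: str


def bone_mask(vol: VolumeImage, lo: float = 600.0, hi: float = 1600.0) -> VolumeImage:
    """Binary mask of voxels in the expected bone intensity window.

    A one-voxel-radius morphological opening removes speckle (isolated noise
    voxels that happen to land in the window).
    """
    if lo >= hi:
        raise ConfigError(f"bone window lo {lo} must be < hi {hi}")
    raw = (vol.voxels >= lo) & (vol.voxels <= hi)
    structure = ndimage.generate_binary_structure(3, 1)
    # opening with the border treated as filled: voxels at the volume edge are
    # not speckle just because the grid ends there
    eroded = ndimage.binary_erosion(raw, structure=structure, border_value=1)
    opened = ndimage.binary_dilation(eroded, structure=structure)
    if not opened.any():
        raise EmptyMaskError(
            f"bone window [{lo}, {hi}] selects no voxels; registration cannot proceed")
    return vol.with_voxels(opened.astype(np.uint8))


def dilate_mask(mask: VolumeImage, iterations: int = 2) -> VolumeImage:
    """Grow a binary mask; used to let masked MI see the structure's edges.

    A mask cut exactly at the bone boundary can exclude the high-contrast
    bone/soft-tissue transition that carries most of the alignment
    information; a couple of voxels of dilation brings it back in.
    """
    grown = ndimage.binary_dilation(
        mask.voxels > 0, structure=ndimage.generate_binary_structure(3, 1),
        iterations=iterations)
    return mask.with_voxels(grown.astype(np.uint8))


def _mask_com_world(mask: VolumeImage) -> np.ndarray:
    idx = np.argwhere(mask.voxels > 0)
    if len(idx) == 0:
        raise EmptyMaskError("mask contains no voxels")
    return mask.index_to_world(idx.astype(float)).mean(axis=0)


def com_align(fixed_mask: VolumeImage, moving_mask: VolumeImage) -> RigidTransform:
    """Pure translation mapping the moving mask's center of mass onto the fixed one's."""
    t = _mask_com_world(fixed_mask) - _mask_com_world(moving_mask)
    return RigidTransform(np.array([1.0, 0, 0, 0]), t, moving_mask.frame, fixed_mask.frame)


# -- SimpleITK bridge ---------------------------------------------------------


def _to_sitk_float(vol: VolumeImage) -> sitk.Image:
    img = vol.to_sitk()
    return sitk.Cast(img, sitk.sitkFloat32)


def _to_sitk_mask(mask: VolumeImage) -> sitk.Image:
    return sitk.Cast(mask.to_sitk(), sitk.sitkUInt8)


def _euler_from_rigid(t_fixed_to_moving: RigidTransform, center: np.ndarray) -> sitk.Euler3DTransform:
    e = sitk.Euler3DTransform()
    e.SetCenter(tuple(center))
    e.SetMatrix(tuple(t_fixed_to_moving.rotation_matrix.flatten()), 1e-8)
    # full map: y = R (x - c) + c + t  =>  offset t = T(c) - c
    e.SetTranslation(tuple(t_fixed_to_moving.apply(center) - center))
    return e


def _rigid_from_sitk(tr: sitk.Transform, frame_from: str, frame_to: str) -> RigidTransform:
    e = sitk.Euler3DTransform(tr)
    r = np.array(e.GetMatrix()).reshape(3, 3)
    c = np.array(e.GetCenter())
    t = np.array(e.GetTranslation())
    full_t = t + c - r @ c
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = full_t
    return RigidTransform.from_matrix(m, frame_from, frame_to)


def register_mi(
    fixed: VolumeImage,
    moving: VolumeImage,
    init: RigidTransform,
    fixed_mask: Optional[VolumeImage] = None,
    moving_mask: Optional[VolumeImage] = None,
    params: Optional[RegistrationParams] = None,
) -> MIResult:
    """Masked mutual-information rigid registration.

    ``init`` maps the moving frame into the fixed frame (e.g. the COM
    alignment of the bone masks); the returned transform refines it.  The
    metric is Mattes mutual information (reported value is negative MI, lower
    is better) evaluated on every voxel of the fixed grid inside the fixed
    mask — no stochastic sampling, so results are reproducible bit for bit.
    """
    params = params or RegistrationParams()
    if init.frame_from != moving.frame or init.frame_to != fixed.frame:
        raise FrameError(
            f"init maps '{init.frame_from}'->'{init.frame_to}' but volumes are "
            f"'{moving.frame}' (moving) and '{fixed.frame}' (fixed)")
    if fixed_mask is not None and moving_mask is not None:
        # overlap sanity check: moving-mask COM mapped by init must land within
        # the fixed volume bounds, else the initialization is unusable
        com = init.apply(_mask_com_world(moving_mask))
        idx = fixed.world_to_index(com)
        if np.any(idx < -0.5) or np.any(idx > np.asarray(fixed.shape) - 0.5):
            raise ConfigError(
                "no mask overlap under the initial transform: moving mask maps "
                f"outside the fixed volume (index {np.round(idx, 1)})")

    n_threads_before = sitk.ProcessObject.GetGlobalDefaultNumberOfThreads()
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    try:
        f_img = _to_sitk_float(fixed)
        m_img = _to_sitk_float(moving)
        center = _mask_com_world(fixed_mask) if fixed_mask is not None else \
            fixed.index_to_world((np.asarray(fixed.shape, float) - 1) / 2.0)
        initial = _euler_from_rigid(init.invert(), center)

        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.bins)
        reg.SetMetricSamplingStrategy(reg.NONE)
        if fixed_mask is not None:
            reg.SetMetricFixedMask(_to_sitk_mask(fixed_mask))
        if moving_mask is not None:
            reg.SetMetricMovingMask(_to_sitk_mask(moving_mask))
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=params.learning_rate,
            minStep=params.min_step,
            numberOfIterations=params.max_iterations,
            relaxationFactor=params.relaxation_factor,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(params.shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(params.smoothing_sigmas))
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        reg.SetInitialTransform(initial, inPlace=True)
        final = reg.Execute(f_img, m_img)
        stop = reg.GetOptimizerStopConditionDescription()
        converged = "maximum number of iterations" not in stop.lower()
        transform = _rigid_from_sitk(final, fixed.frame, moving.frame).invert()
        return MIResult(
            transform=transform,
            metric=float(reg.GetMetricValue()),
            converged=converged,
            iterations=int(reg.GetOptimizerIteration()),
            stop_condition=stop,
        )
    finally:
        sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(n_threads_before)


def evaluate_metric(
    fixed: VolumeImage,
    moving: VolumeImage,
    transform: RigidTransform,
    fixed_mask: Optional[VolumeImage] = None,
    moving_mask: Optional[VolumeImage] = None,
    params: Optional[RegistrationParams] = None,
) -> float:
    """Mattes metric value (negative MI) at a fixed transform, full sampling."""
    params = params or RegistrationParams()
    n_before = sitk.ProcessObject.GetGlobalDefaultNumberOfThreads()
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    try:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=params.bins)
        reg.SetMetricSamplingStrategy(reg.NONE)
        if fixed_mask is not None:
            reg.SetMetricFixedMask(_to_sitk_mask(fixed_mask))
        if moving_mask is not None:
            reg.SetMetricMovingMask(_to_sitk_mask(moving_mask))
        reg.SetInterpolator(sitk.sitkLinear)
        center = fixed.index_to_world((np.asarray(fixed.shape, float) - 1) / 2.0)
        reg.SetInitialTransform(_euler_from_rigid(transform.invert(), center),
                                inPlace=True)
        return float(reg.MetricEvaluate(_to_sitk_float(fixed), _to_sitk_float(moving)))
    finally:
        sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(n_before)


def roi_mask(vol: VolumeImage, roi_lo, roi_hi) -> VolumeImage:
    """Binary mask of the voxels whose centers lie in an axis-aligned world box."""
    lo = np.asarray(roi_lo, float)
    hi = np.asarray(roi_hi, float)
    if np.any(lo >= hi):
        raise ConfigError(f"ROI box is empty: lo {lo} hi {hi}")
    axes = [vol.origin[a] + vol.spacing[a] * np.arange(vol.shape[a]) for a in range(3)]
    inside = np.ones(vol.shape, dtype=bool)
    for a in range(3):
        ax_ok = (axes[a] >= lo[a]) & (axes[a] <= hi[a])
        shape = [1, 1, 1]
        shape[a] = -1
        inside &= ax_ok.reshape(shape)
    if not inside.any():
        raise ConfigError("ROI box does not intersect the volume")
    return vol.with_voxels(inside.astype(np.uint8))


def register_roi(
    fixed: VolumeImage,
    moving: VolumeImage,
    roi_lo,
    roi_hi,
    init: Optional[RigidTransform] = None,
    params: Optional[RegistrationParams] = None,
    manual: Optional[RigidTransform] = None,
) -> MIResult:
    """ROI-restricted rigid registration (the preoperative-model link).

    The clinical step aligned the preoperative MRI to the contrast CBCT
    manually, using only the vascular anatomy around the target lesion (local
    rigidity holds near the lesion even when the whole organ deformed).
    ``manual`` reproduces that: a supplied transform is validated and passed
    through verbatim.  Otherwise MI registration restricted to the ROI box
    runs from ``init`` (identity by default).
    """
    if manual is not None:
        if manual.frame_from != moving.frame or manual.frame_to != fixed.frame:
            raise FrameError(
                f"manual transform maps '{manual.frame_from}'->'{manual.frame_to}', "
                f"expected '{moving.frame}'->'{fixed.frame}'")
        return MIResult(transform=manual, metric=float("nan"), converged=True,
                        iterations=0, stop_condition="manual pass-through")
    if init is None:
        m = np.eye(4)
        init = RigidTransform.from_matrix(m, moving.frame, fixed.frame)
    fixed_mask = roi_mask(fixed, roi_lo, roi_hi)
    return register_mi(fixed, moving, init, fixed_mask=fixed_mask, params=params)
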