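"""Rasterize phantom scenes into CT/CBCT/MRI-like volumes.

Intensities are constant per tissue class (CT-like values approximate
Hounsfield units but make no CT-physics claim; detection and registration
need only ordinal contrast).  Metal (surgical clips, tracker sensor discs) is
a single saturated class rendered with partial-volume weighting from its
signed distance function, which is what gives detection its sub-voxel
centroid accuracy target.

The CBCT modality reproduces the C-arm field-of-view geometry: a fully
sampled cylinder of Ø 25 cm x 20 cm, and an optional truncated-projection
preset extending to a 35 x 35 x 20 cm box whose peripheral voxels are
degraded (extra noise + intensity bias), not deleted — they remain usable for
high-contrast landmarks such as the patient trackers, and for nothing else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .phantom import PhantomScene
from .volume import VolumeImage

log = logging.getLogger(__name__)

# tissue-class intensities per modality; bone is a (marrow, cortical) ramp —
# darker core, bright shell — so bone has internal structure, as in real CT
INTENSITY = {
    "ct": {"air": -1000.0, "soft": 50.0, "liver": 100.0, "vessel": 300.0,
           "tumor": 160.0, "bone": (700.0, 1500.0), "metal": 3000.0},
    "cbct": {"air": -1000.0, "soft": 50.0, "liver": 100.0, "vessel": 300.0,
             "tumor": 160.0, "bone": (700.0, 1500.0), "metal": 3000.0},
    # arbitrary but consistent T1-like ordering; only the class<->class
    # correspondence matters for mutual information
    "mri": {"air": 0.0, "soft": 300.0, "liver": 450.0, "vessel": 700.0,
            "tumor": 600.0, "bone": (150.0, 120.0), "metal": 80.0},
}

NOISE_SIGMA = {"ct": 12.0, "cbct": 20.0, "mri": 15.0}

LABEL_IDS = {"air": 0, "soft": 1, "liver": 2, "vessel": 3, "tumor": 4,
             "bone": 5, "metal": 6}

ALL_GROUPS = frozenset({"torso", "liver", "vessels", "tumors", "ribs", "clips", "discs"})
PREOP_GROUPS = frozenset({"torso", "liver", "vessels", "tumors", "ribs"})

FULLY_SAMPLED_DIAMETER = 250.0  # mm, Ø 25 cm
TRUNCATION_NOISE_FACTOR = 5.0
TRUNCATION_BIAS = 30.0


@dataclass(frozen=True)
class FieldOfView:
    """Axis-aligned reconstruction box; optionally with the CBCT cylinder."""

    center: tuple
    size: tuple
    cylindrical: bool = False
    truncated: bool = False


def cbct_standard_fov(center=(0.0, 25.0, 0.0)) -> FieldOfView:
    return FieldOfView(center, (250.0, 250.0, 200.0), cylindrical=True, truncated=False)


def cbct_truncated_fov(center=(0.0, 25.0, 0.0)) -> FieldOfView:
    return FieldOfView(center, (350.0, 350.0, 200.0), cylindrical=True, truncated=True)


def ct_fov(center=(0.0, 5.0, 0.0)) -> FieldOfView:
    return FieldOfView(center, (360.0, 320.0, 220.0))


def mri_fov(center=(0.0, 0.0, 0.0)) -> FieldOfView:
    return FieldOfView(center, (300.0, 240.0, 160.0))


def _make_grid(fov: FieldOfView, spacing, frame: str) -> VolumeImage:
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be positive, got {spacing}")
    shape = np.maximum(np.round(np.asarray(fov.size, float) / spacing).astype(int), 1)
    origin = np.asarray(fov.center, float) - (shape - 1) * spacing / 2.0
    vox = np.empty(tuple(shape), dtype=np.float32)
    return VolumeImage(vox, spacing, origin, np.eye(3), frame)


def _subgrid_points(vol: VolumeImage, bounds: np.ndarray):
    """Index slices + world points (chunk-iterable) of the voxels inside bounds."""
    lo = np.floor(vol.world_to_index(bounds[0])).astype(int)
    hi = np.ceil(vol.world_to_index(bounds[1])).astype(int) + 1
    lo = np.clip(lo, 0, np.asarray(vol.shape))
    hi = np.clip(hi, 0, np.asarray(vol.shape))
    if np.any(lo >= hi):
        return None, None
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [vol.origin[a] + vol.spacing[a] * np.arange(lo[a], hi[a]) for a in range(3)]
    return sl, axes


def _eval_on_subgrid(fn, axes, chunk_planes: int = 64) -> np.ndarray:
    """Evaluate fn(points (N,3)) -> (N,) over the subgrid, chunked along x."""
    nx, ny, nz = len(axes[0]), len(axes[1]), len(axes[2])
    out = np.empty((nx, ny, nz))
    yy, zz = np.meshgrid(axes[1], axes[2], indexing="ij")
    base = np.column_stack([np.zeros(yy.size), yy.ravel(), zz.ravel()])
    for i0 in range(0, nx, chunk_planes):
        i1 = min(i0 + chunk_planes, nx)
        pts = np.tile(base, (i1 - i0, 1))
        pts[:, 0] = np.repeat(axes[0][i0:i1], yy.size)
        out[i0:i1] = fn(pts).reshape(i1 - i0, ny, nz)
    return out


def _paint_solid(vol, labels, primitive, value: float, label: int) -> int:
    sl, axes = _subgrid_points(vol, primitive.bounds())
    if sl is None:
        return 0
    inside = _eval_on_subgrid(primitive.contains, axes).astype(bool)
    vol.voxels[sl][inside] = value
    labels[sl][inside] = label
    return int(np.count_nonzero(inside))


def _paint_bone(vol, labels, capsule, marrow: float, cortical: float) -> None:
    """Bone tube with a radial profile: marrow core ramping to a cortical shell."""
    sl, axes = _subgrid_points(vol, capsule.bounds())
    if sl is None:
        return
    dist = _eval_on_subgrid(capsule.distance, axes)
    inside = dist <= capsule.radius
    frac = np.clip(dist / capsule.radius, 0.0, 1.0)
    value = marrow + (cortical - marrow) * frac**2
    vol.voxels[sl][inside] = value[inside]
    labels[sl][inside] = LABEL_IDS["bone"]


def _paint_metal(vol, labels, sdf_fn, bounds, value: float, feather: float) -> None:
    """Partial-volume metal: occupancy = clip(0.5 - sdf/feather, 0, 1)."""
    sl, axes = _subgrid_points(vol, bounds)
    if sl is None:
        return
    occ = np.clip(0.5 - _eval_on_subgrid(sdf_fn, axes) / feather, 0.0, 1.0)
    sub = vol.voxels[sl]
    vol.voxels[sl] = sub * (1 - occ) + value * occ
    labels[sl][occ > 0.5] = LABEL_IDS["metal"]


def render_volume(
    scene: PhantomScene,
    spacing,
    fov: FieldOfView,
    modality: str = "ct",
    seed: int = 0,
    noise_sigma: Optional[float] = None,
    include: Optional[Iterable[str]] = None,
    with_labels: bool = False,
):
    """Render the scene onto an axis-aligned grid in the scene's frame.

    ``include`` restricts which structure groups are rasterized (a
    preoperative CT/MRI has no intraoperative metal); default is everything
    present in the scene.  Returns a :class:`VolumeImage`, plus an integer
    class-label volume when ``with_labels`` is set (ground truth for tests).
    """
    if modality not in INTENSITY:
        raise ValueError(f"unknown modality '{modality}'")
    values = INTENSITY[modality]
    sigma = NOISE_SIGMA[modality] if noise_sigma is None else float(noise_sigma)
    groups = ALL_GROUPS if include is None else frozenset(include)

    vol = _make_grid(fov, spacing, scene.frame)
    vol.voxels.fill(values["air"])
    labels = np.zeros(vol.shape, dtype=np.uint8)
    prim = scene.primitives

    if "discs" in groups:
        box_lo = np.asarray(fov.center) - np.asarray(fov.size) / 2.0
        box_hi = np.asarray(fov.center) + np.asarray(fov.size) / 2.0
        outside = [i for i, d in enumerate(prim["discs"])
                   if np.any(d.center < box_lo) or np.any(d.center > box_hi)]
        if outside:
            log.warning(
                "tracker discs %s fall outside the %s field of view and will "
                "not be imaged", outside, modality)

    if "torso" in groups:
        _paint_solid(vol, labels, prim["torso"], values["soft"], LABEL_IDS["soft"])
    if "ribs" in groups:
        marrow, cortical = values["bone"]
        for rib in prim["ribs"]:
            for seg in rib:
                _paint_bone(vol, labels, seg, marrow, cortical)
    if "liver" in groups:
        _paint_solid(vol, labels, prim["liver"], values["liver"], LABEL_IDS["liver"])
    if "vessels" in groups:
        for c in prim["vessels"]:
            _paint_solid(vol, labels, c, values["vessel"], LABEL_IDS["vessel"])
    if "tumors" in groups:
        for s in prim["tumors"]:
            _paint_solid(vol, labels, s, values["tumor"], LABEL_IDS["tumor"])

    feather = float(np.mean(vol.spacing))
    if "clips" in groups:
        for c in prim["clips"]:
            _paint_metal(vol, labels, lambda p, c=c: c.distance(p) - c.radius,
                         c.bounds(), values["metal"], feather)
    if "discs" in groups:
        for d in prim["discs"]:
            _paint_metal(vol, labels, d.sdf, d.bounds(), values["metal"], feather)

    rng = np.random.default_rng(seed)
    if sigma > 0:
        vol.voxels += rng.normal(0.0, sigma, vol.shape).astype(np.float32)

    if modality == "cbct" and fov.cylindrical:
        gx = vol.origin[0] + vol.spacing[0] * np.arange(vol.shape[0]) - fov.center[0]
        gy = vol.origin[1] + vol.spacing[1] * np.arange(vol.shape[1]) - fov.center[1]
        r2 = gx[:, None] ** 2 + gy[None, :] ** 2
        outside_cyl = (r2 > (FULLY_SAMPLED_DIAMETER / 2.0) ** 2)[:, :, None]
        outside_cyl = np.broadcast_to(outside_cyl, vol.shape)
        if fov.truncated:
            extra = rng.normal(0.0, TRUNCATION_NOISE_FACTOR * sigma, vol.shape)
            vol.voxels = np.where(
                outside_cyl, vol.voxels + TRUNCATION_BIAS + extra, vol.voxels
            ).astype(np.float32)
        else:
            vol.voxels = np.where(outside_cyl, values["air"], vol.voxels).astype(np.float32)
            labels[np.broadcast_to(outside_cyl, vol.shape)] = LABEL_IDS["air"]

    if with_labels:
        return vol, vol.with_voxels(labels)
    return vol
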