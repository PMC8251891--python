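"""Detect metal fiducials (surgical clips, tracker sensor discs) in volumes.

Metal renders far above bone, so detection is supra-threshold connected
components (26-connectivity), size-filtered in physical volume, with
intensity-weighted centroids in world millimetres (weighting roughly halves
the quantization error of a binary centroid).  Discs are told from clips by
component volume: a clip is a couple of cubic millimetres of wire, a sensor
disc is a Ø 8 x 2 mm cylinder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage

from .errors import CardinalityError, ConfigError, GroupingError
from .fiducials import match_correspondence
from .volume import VolumeImage

log = logging.getLogger(__name__)

METAL_THRESHOLD = 2000.0  # between bone (<= ~1500) and metal (~3000)
DISC_VOLUME_RANGE = (50.0, 300.0)  # mm^3
CLIP_VOLUME_RANGE = (1.0, 20.0)  # mm^3


@dataclass(frozen=True)
class BlobDetection:
    center: np.ndarray  # world mm, intensity-weighted centroid
    volume_mm3: float
    peak_intensity: float
    principal_axes_mm: tuple  # lengths, sorted descending

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        if self.volume_mm3 <= 0:
            raise ValueError("blob volume must be positive")


@dataclass(frozen=True)
class TrackerLayout:
    """3 patient trackers x 2 disc-sensor centers, world mm."""

    centers: np.ndarray  # (6,3): tracker k owns rows 2k, 2k+1
    pairing_distance: float

    def __post_init__(self):
        c = np.asarray(self.centers, float).reshape(6, 3)
        object.__setattr__(self, "centers", c)
        for k in range(3):
            d = float(np.linalg.norm(c[2 * k] - c[2 * k + 1]))
            if abs(d - self.pairing_distance) > 2.0:
                raise GroupingError(
                    f"tracker {k} disc distance {d:.2f} mm is outside "
                    f"{self.pairing_distance} +/- 2 mm")

    @property
    def pairs(self) -> tuple:
        return tuple((self.centers[2 * k], self.centers[2 * k + 1]) for k in range(3))


def detect_metal_blobs(
    vol: VolumeImage,
    threshold: float = METAL_THRESHOLD,
    min_vol: float = 1.0,
    max_vol: float = 500.0,
    merge_distance: float = 0.0,
) -> list[BlobDetection]:
    """Connected supra-threshold components, size-filtered, brightest first.

    ``merge_distance`` > 0 merges components whose centroids lie within that
    distance before the size filter: partial-volume sampling can split one
    thin metal object (a clip wire) into fragments, which must be counted as
    one marker, not two.
    """
    supra = vol.voxels > threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(supra, structure=structure)
    voxel_volume = float(np.prod(vol.spacing))
    components = []  # (index array,) per component
    for lab in range(1, n + 1):
        components.append(np.argwhere(labeled == lab))
    if merge_distance > 0 and len(components) > 1:
        centroids = np.array([
            vol.index_to_world(idx.astype(float)).mean(axis=0) for idx in components])
        parent = list(range(len(components)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(components)):
            for j in range(i + 1, len(components)):
                if np.linalg.norm(centroids[i] - centroids[j]) <= merge_distance:
                    parent[find(i)] = find(j)
        merged: dict[int, list] = {}
        for i, idx in enumerate(components):
            merged.setdefault(find(i), []).append(idx)
        components = [np.vstack(group) for group in merged.values()]

    blobs: list[BlobDetection] = []
    for idx in components:
        volume = len(idx) * voxel_volume
        if not (min_vol <= volume <= max_vol):
            log.info("component (%.1f mm^3) outside [%g, %g] mm^3 - filtered",
                     volume, min_vol, max_vol)
            continue
        weights = vol.voxels[tuple(idx.T)].astype(float)
        weights = np.maximum(weights - threshold, 0.0) + 1e-9
        world = vol.index_to_world(idx.astype(float))
        center = np.average(world, axis=0, weights=weights)
        centered = world - center
        cov = (centered * weights[:, None]).T @ centered / weights.sum()
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        axes = tuple(float(2.0 * np.sqrt(max(v, 0.0))) for v in eigvals)
        blobs.append(BlobDetection(center, volume, float(weights.max() + threshold), axes))
    blobs.sort(key=lambda b: -b.peak_intensity)
    return blobs


def group_into_trackers(
    blobs: list[BlobDetection],
    pairing_distance: float = 20.0,
    tol: float = 2.0,
) -> TrackerLayout:
    """Select 6 blobs forming 3 disjoint pairs at the configured disc spacing.

    Exhaustive over candidate pairings, minimizing the summed deviation
    ``|d - pairing_distance|``; clip misdetections and other stray blobs are
    excluded automatically because they pair with nothing at the right
    distance.  Ties resolve to the lexicographically smallest pair-index
    combination (blob sort order).
    """
    if len(blobs) < 6:
        raise GroupingError(f"need >= 6 blobs to form 3 tracker pairs, got {len(blobs)}")
    centers = np.array([b.center for b in blobs])
    edges = []  # (i, j, deviation)
    for i, j in combinations(range(len(blobs)), 2):
        d = float(np.linalg.norm(centers[i] - centers[j]))
        dev = abs(d - pairing_distance)
        if dev <= tol:
            edges.append((i, j, dev))
    best = None  # (total deviation, pair index tuple)
    for combo in combinations(range(len(edges)), 3):
        used: set = set()
        ok = True
        total = 0.0
        for e in combo:
            i, j, dev = edges[e]
            if i in used or j in used:
                ok = False
                break
            used.update((i, j))
            total += dev
        if ok and (best is None or total < best[0] - 1e-12):
            best = (total, combo)
    if best is None:
        dists = sorted(
            float(np.linalg.norm(centers[i] - centers[j]))
            for i, j in combinations(range(len(blobs)), 2))
        raise GroupingError(
            f"no 3 disjoint pairs within {tol} mm of {pairing_distance} mm; "
            f"candidate distances: {np.round(dists, 1).tolist()}")
    ordered = []
    for e in best[1]:
        i, j, _ = edges[e]
        ordered.extend([centers[i], centers[j]])
    return TrackerLayout(np.array(ordered), pairing_distance)


def detect_clips(vol: VolumeImage, roi_lo, roi_hi,
                 threshold: float = METAL_THRESHOLD) -> np.ndarray:
    """Clip centers (world mm) inside the liver bounding box.

    Restricting to the liver region keeps the tracker discs (and any other
    metal outside the organ) out of the clip list; the clip-scale volume
    filter removes disc fragments that might still intrude.
    """
    lo = np.asarray(roi_lo, float)
    hi = np.asarray(roi_hi, float)
    if np.any(lo >= hi):
        raise ConfigError(f"empty clip ROI: lo {lo} hi {hi}")
    lo_idx = np.clip(np.floor(vol.world_to_index(lo)).astype(int), 0, np.asarray(vol.shape))
    hi_idx = np.clip(np.ceil(vol.world_to_index(hi)).astype(int) + 1, 0, np.asarray(vol.shape))
    if np.any(lo_idx >= hi_idx):
        raise ConfigError("clip ROI does not intersect the volume")
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo_idx, hi_idx))
    sub = VolumeImage(
        vol.voxels[sl],
        vol.spacing.copy(),
        vol.index_to_world(lo_idx.astype(float)),
        vol.direction.copy(),
        vol.frame,
    )
    blobs = detect_metal_blobs(sub, threshold=threshold,
                               min_vol=CLIP_VOLUME_RANGE[0], max_vol=CLIP_VOLUME_RANGE[1],
                               merge_distance=3.0)
    return np.array([b.center for b in blobs]).reshape(-1, 3)


def truncation_consistency(centers_full, centers_trunc) -> tuple[np.ndarray, float]:
    """Per-center displacement between full and truncated-FOV reconstructions.

    The geometric-distortion QC statistic of the extended reconstruction:
    centers are matched by best-FRE correspondence, then compared directly
    (both lists live in the same scanner frame, so no alignment is applied).
    Returns (per-point displacements mm, mean mm).
    """
    full = np.asarray(centers_full, float).reshape(-1, 3)
    trunc = np.asarray(centers_trunc, float).reshape(-1, 3)
    if len(full) != len(trunc):
        raise CardinalityError(
            f"{len(full)} centers in full vs {len(trunc)} in truncated reconstruction")
    fids = match_correspondence(full, trunc, frame_src="cbct_full", frame_dst="cbct_trunc")
    disp = np.linalg.norm(fids.positions_dst - fids.positions_src, axis=1)
    return disp, float(disp.mean())
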