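"""Accuracy assessment: image distances, navigation-vs-image statistics, TRE.

The clinical accuracy measure pairs, per surgical clip, the shortest
clip-to-tumor distance reported by the navigation system against the same
distance measured on the verification CBCT by observers; the statistic is
mean +/- SD of the absolute difference together with the Pearson correlation
of the two distance sets.  Repeat-measurement spread (range of repeated
measurements of one point) quantifies observer variability.  TRE profiling
by distance from the liver sensor is the phantom-only measurement that the
clinical system cannot make: it tests the semi-rigid zone assumption
directly against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage, stats

from .errors import CardinalityError
from .meshdist import MeshDistanceQuery
from .navigation import NavigationState
from .volume import VolumeImage

DEFAULT_TRE_BINS = (0.0, 25.0, 50.0, 100.0, np.inf)


@dataclass(frozen=True)
class AccuracyRecord:
    """Paired navigation vs image distance at one clip marker."""

    marker_id: str
    d_nav: float
    d_img: Optional[float] = None
    observer_values: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "observer_values", tuple(float(v) for v in self.observer_values))
        if self.d_nav < 0:
            raise ValueError(f"negative navigation distance for {self.marker_id}")
        d_img = self.d_img
        if self.observer_values:
            mean_obs = float(np.mean(self.observer_values))
            if d_img is None:
                d_img = mean_obs
            elif abs(d_img - mean_obs) > 1e-6:
                raise ValueError(
                    f"{self.marker_id}: d_img {d_img} is not the mean of the "
                    f"observer values ({mean_obs})")
        if d_img is None:
            raise ValueError(f"{self.marker_id}: need d_img or observer values")
        if d_img < 0:
            raise ValueError(f"negative image distance for {self.marker_id}")
        object.__setattr__(self, "d_img", float(d_img))


def image_distance(clip_center, tumor: Union[trimesh.Trimesh, VolumeImage]) -> float:
    """Distance (mm) from a clip center to the tumor edge on the image.

    Mesh mode: exact point-to-triangle distance, 0 inside.  Mask mode (the
    reproducible surrogate for an observer judging the visible tumor edge):
    distance to the nearest boundary voxel center of the segmentation, 0 for
    clips inside the segmented tumor.
    """
    p = np.asarray(clip_center, float).reshape(3)
    if isinstance(tumor, trimesh.Trimesh):
        if tumor.faces.shape[0] == 0:
            raise ValueError("empty tumor mesh")
        query = MeshDistanceQuery(tumor)
        if tumor.is_watertight and query.contains(p[None])[0]:
            return 0.0
        return float(query.closest(p[None])[0][0])
    mask = tumor.voxels > 0
    if not mask.any():
        raise ValueError("empty tumor segmentation")
    idx = np.round(tumor.world_to_index(p)).astype(int)
    if np.all(idx >= 0) and np.all(idx < np.asarray(tumor.shape)) and mask[tuple(idx)]:
        return 0.0
    boundary = mask & ~ndimage.binary_erosion(mask)
    bpts = tumor.index_to_world(np.argwhere(boundary).astype(float))
    return float(np.min(np.linalg.norm(bpts - p, axis=1)))


def accuracy_stats(records: Sequence[AccuracyRecord]) -> dict:
    """Summary statistics of paired navigation/image distances.

    Returns mean and SD (sample) of |d_nav - d_img|, the Pearson correlation
    between the two distance sets with its two-sided p-value (t-distribution,
    n - 2 df), and n.  With zero variance in either variable the correlation
    is undefined and flagged rather than fabricated.
    """
    if len(records) < 3:
        raise CardinalityError(f"need >= 3 records for accuracy statistics, got {len(records)}")
    d_nav = np.array([r.d_nav for r in records])
    d_img = np.array([r.d_img for r in records])
    diff = np.abs(d_nav - d_img)
    out = {
        "n": len(records),
        "mean_abs_diff": float(diff.mean()),
        "sd": float(diff.std(ddof=1)),
        "pearson_r": float("nan"),
        "p_value": float("nan"),
        "correlation_defined": True,
    }
    if np.ptp(d_nav) == 0 or np.ptp(d_img) == 0:
        out["correlation_defined"] = False
        return out
    r, p = stats.pearsonr(d_nav, d_img)
    out["pearson_r"] = float(r)
    out["p_value"] = float(p)
    return out


def repeat_variability(measurements: Sequence[tuple]) -> dict:
    """Spread (max - min) of repeated measurements per point, and its mean."""
    if not measurements:
        raise CardinalityError("no measurements")
    per_point = {}
    for point_id, values in measurements:
        vals = np.asarray(values, float)
        if vals.size < 2:
            raise CardinalityError(
                f"point {point_id!r} has {vals.size} repeat(s); need >= 2")
        per_point[point_id] = float(np.ptp(vals))
    return {
        "per_point_spread": per_point,
        "mean_spread": float(np.mean(list(per_point.values()))),
    }


def tre_profile(
    states: Sequence[NavigationState],
    model_points,
    true_positions_em: Sequence,
    bins: tuple = DEFAULT_TRE_BINS,
) -> pd.DataFrame:
    """Target registration error binned by snapshot distance from the sensor.

    ``model_points`` (model frame) are located through each navigation state
    and compared with their true EM positions (phantom ground truth, one
    (N,3) array per state).  Binning uses each point's distance from the
    sensor at the snapshot — the geometry the target-zone radius is defined
    on.  Returns a table with bin edges, n, mean TRE and SD.
    """
    pts = np.asarray(model_points, float).reshape(-1, 3)
    if len(states) != len(true_positions_em):
        raise CardinalityError(
            f"{len(states)} states vs {len(true_positions_em)} ground-truth arrays")
    chain = states[0].chain
    snapshot_pos = chain.static_model_to_em.apply(pts)
    dist_from_sensor = np.linalg.norm(snapshot_pos - chain.s_ref.position, axis=1)

    tre = np.empty((len(states), len(pts)))
    for i, (state, truth) in enumerate(zip(states, true_positions_em)):
        located = state.model_to_em_live.apply(pts)
        tre[i] = np.linalg.norm(located - np.asarray(truth, float).reshape(-1, 3), axis=1)

    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (dist_from_sensor >= lo) & (dist_from_sensor < hi)
        vals = tre[:, sel].ravel()
        rows.append({
            "bin_lo_mm": lo,
            "bin_hi_mm": hi,
            "n_points": int(sel.sum()),
            "n_samples": vals.size,
            "mean_tre_mm": float(vals.mean()) if vals.size else float("nan"),
            "sd_tre_mm": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        })
    return pd.DataFrame(rows)
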