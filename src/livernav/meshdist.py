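"""Exact point-to-surface distance and containment for triangle meshes.

The guidance-critical query — shortest distance from the pointer tip to the
tracked tumor surface — is the exact minimum point-to-triangle distance over
the mesh.  A k-d tree over triangle centroids supplies an upper bound from
the nearest centroid, which prunes the candidate set before the exact
per-triangle computation; the result is identical to evaluating every
triangle, just cheaper.

Containment uses ray-crossing parity with a fixed oblique ray direction
(watertight meshes only).
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

# oblique, irrational-ish direction: avoids rays lying in a triangle's plane
# for the axis-aligned and icosphere geometry used throughout
_RAY_DIR = np.array([0.57735026919, 0.54772255751, 0.60553007082])
_RAY_DIR = _RAY_DIR / np.linalg.norm(_RAY_DIR)


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point to ``p`` on each triangle (T,3,3); returns (dist (T,), points (T,3)).

    Region-based closest-point-on-triangle (vertex / edge / face cases),
    vectorized over triangles.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    region_a = (d1 <= 0) & (d2 <= 0)
    out[region_a] = a[region_a]
    done |= region_a

    region_b = ~done & (d3 >= 0) & (d4 <= d3)
    out[region_b] = b[region_b]
    done |= region_b

    vc = d1 * d4 - d3 * d2
    on_ab = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(np.abs(d1 - d3) > 1e-300, d1 - d3, 1.0)
    v = np.clip(d1 / denom, 0.0, 1.0)
    out[on_ab] = a[on_ab] + v[on_ab, None] * ab[on_ab]
    done |= on_ab

    region_c = ~done & (d6 >= 0) & (d5 <= d6)
    out[region_c] = c[region_c]
    done |= region_c

    vb = d5 * d2 - d1 * d6
    on_ac = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(np.abs(d2 - d6) > 1e-300, d2 - d6, 1.0)
    w = np.clip(d2 / denom, 0.0, 1.0)
    out[on_ac] = a[on_ac] + w[on_ac, None] * ac[on_ac]
    done |= on_ac

    va = d3 * d6 - d5 * d4
    on_bc = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom_bc = (d4 - d3) + (d5 - d6)
    denom_bc = np.where(np.abs(denom_bc) > 1e-300, denom_bc, 1.0)
    w = np.clip((d4 - d3) / denom_bc, 0.0, 1.0)
    out[on_bc] = b[on_bc] + w[on_bc, None] * (c[on_bc] - b[on_bc])
    done |= on_bc

    interior = ~done
    denom_f = va + vb + vc
    denom_f = np.where(np.abs(denom_f) > 1e-300, denom_f, 1.0)
    v = vb / denom_f
    w = vc / denom_f
    out[interior] = (a[interior] + v[interior, None] * ab[interior]
                     + w[interior, None] * ac[interior])
    return np.linalg.norm(p - out, axis=1), out


class MeshDistanceQuery:
    """Reusable exact-distance query against one mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise ValueError("mesh has no faces")
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        self.centroids = self.triangles.mean(axis=1)
        self.radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2).max(axis=1)
        self._tree = cKDTree(self.centroids)

    def closest(self, points) -> tuple[np.ndarray, np.ndarray]:
        """(distances (N,), foot points (N,3)) — exact, pruned by the k-d tree."""
        pts = np.atleast_2d(np.asarray(points, float))
        dists = np.empty(len(pts))
        feet = np.empty((len(pts), 3))
        d_near, i_near = self._tree.query(pts)
        for k, p in enumerate(pts):
            upper = d_near[k] + self.radii[i_near[k]]
            lower = np.linalg.norm(self.centroids - p, axis=1) - self.radii
            cand = lower <= upper + 1e-12
            d, foot = _closest_on_triangles(p, self.triangles[cand])
            j = int(np.argmin(d))
            dists[k] = d[j]
            feet[k] = foot[j]
        return dists, feet

    def contains(self, points) -> np.ndarray:
        """Ray-crossing parity containment (mesh must be watertight)."""
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.zeros(len(pts), dtype=bool)
        tri = self.triangles
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        for k, p in enumerate(pts):
            # Moller-Trumbore against all triangles
            h = np.cross(_RAY_DIR, e2)
            det = np.einsum("ij,ij->i", e1, h)
            ok = np.abs(det) > 1e-12
            inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
            s = p - tri[:, 0]
            u = np.einsum("ij,ij->i", s, h) * inv
            q = np.cross(s, e1)
            v = np.einsum("j,ij->i", _RAY_DIR, q) * inv
            t = np.einsum("ij,ij->i", e2, q) * inv
            hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
            out[k] = (np.count_nonzero(hit) % 2) == 1
        return out


def closest_point_on_mesh(mesh: trimesh.Trimesh, points) -> tuple[np.ndarray, np.ndarray]:
    return MeshDistanceQuery(mesh).closest(points)


def mesh_contains(mesh: trimesh.Trimesh, points) -> np.ndarray:
    return MeshDistanceQuery(mesh).contains(points)
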