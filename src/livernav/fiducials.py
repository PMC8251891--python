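"""Point-based rigid registration between coordinate frames.

This is the solver behind two pipeline links: matching surgical-clip centers
touched with a tracked pointer against their CBCT positions, and matching the
six disc-shaped patient-tracker sensor centers detected in the CBCT against
their live EM positions (minimizing the RMS error of the six points).

The solver is the closed-form cross-covariance SVD (Kabsch/Umeyama) least
squares fit with a determinant guard against reflections — the global optimum
of sum ||R s_i + t - d_i||^2, with no iteration or seed sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np

from .errors import CardinalityError, DegenerateGeometryError
from .geometry import RigidTransform

_AXIS_NAMES = "xyz"


@dataclass(frozen=True)
class FiducialSet:
    """Corresponding fiducial positions in two frames.

    positions_src are expressed in ``frame_src``, positions_dst in
    ``frame_dst``; row i of each corresponds to the same physical marker.
    """

    labels: tuple
    positions_src: np.ndarray
    positions_dst: np.ndarray
    frame_src: str = "src"
    frame_dst: str = "dst"

    def __post_init__(self):
        src = np.asarray(self.positions_src, dtype=float).reshape(-1, 3)
        dst = np.asarray(self.positions_dst, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "positions_src", src)
        object.__setattr__(self, "positions_dst", dst)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(src) != len(dst):
            raise CardinalityError(f"{len(src)} source vs {len(dst)} destination fiducials")
        if len(self.labels) != len(src):
            raise CardinalityError(f"{len(self.labels)} labels for {len(src)} fiducials")
        if len(src) >= 2:
            d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 1e-6:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise DegenerateGeometryError(
                    f"source fiducials {self.labels[i]!r} and {self.labels[j]!r} coincide"
                )

    def __len__(self) -> int:
        return len(self.positions_src)


def _check_geometry(src: np.ndarray, labels) -> None:
    if len(src) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 fiducials for a unique rigid solution, got {len(src)}"
        )
    centered = src - src.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-6 * s[0]:
        # collinear: rotation about the dominant axis is unconstrained
        _, _, vt = np.linalg.svd(centered)
        axis = vt[0] / np.linalg.norm(vt[0])
        ax = _AXIS_NAMES[int(np.argmax(np.abs(axis)))]
        raise DegenerateGeometryError(
            f"fiducials are collinear; rotation about the line (dominant axis "
            f"{ax}, direction {np.round(axis, 3).tolist()}) is unconstrained"
        )


def register_points(fids: FiducialSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform src -> dst and its FRE (mm).

    Returns the transform T minimizing the RMS residual
    ``sqrt(mean ||T(src_i) - dst_i||^2)`` (the fiducial registration error),
    computed in closed form via the SVD of the cross-covariance matrix with a
    sign correction that excludes reflections.
    """
    src, dst = fids.positions_src, fids.positions_dst
    _check_geometry(src, fids.labels)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    cov = (dst - mu_d).T @ (src - mu_s)
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    t = mu_d - r @ mu_s
    transform = RigidTransform.from_matrix(
        np.vstack([np.column_stack([r, t]), [0, 0, 0, 1]]), fids.frame_src, fids.frame_dst
    )
    return transform, fre(transform, fids)


def fre(transform: RigidTransform, fids: FiducialSet) -> float:
    """Fiducial registration error: RMS residual after applying ``transform``."""
    residual = transform.apply(fids.positions_src) - fids.positions_dst
    return float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))


def match_correspondence(
    detected: Sequence, live: Sequence, frame_src: str = "src", frame_dst: str = "dst"
) -> FiducialSet:
    """Assign correspondence between two unlabeled point lists.

    The pipeline detects disc centers in the CBCT in arbitrary order while the
    tracker stream reports them per sensor channel; the assignment is the
    permutation of the live list minimizing the post-registration FRE, found
    by exhaustive search (point counts here are <= 8, so at most 8! = 40320
    candidate registrations).  Ties are broken by the lexicographically
    smallest permutation.
    """
    det = np.asarray(detected, dtype=float).reshape(-1, 3)
    liv = np.asarray(live, dtype=float).reshape(-1, 3)
    if len(det) != len(liv):
        raise CardinalityError(f"{len(det)} detected vs {len(liv)} live points")
    if len(det) > 8:
        raise CardinalityError("exhaustive correspondence search supports at most 8 points")
    best_perm, best_fre = None, np.inf
    for perm in permutations(range(len(det))):  # lexicographic order -> tie rule for free
        fids = FiducialSet(
            labels=tuple(range(len(det))),
            positions_src=det,
            positions_dst=liv[list(perm)],
            frame_src=frame_src,
            frame_dst=frame_dst,
        )
        try:
            _, err = register_points(fids)
        except DegenerateGeometryError:
            raise
        if err < best_fre - 1e-12:
            best_fre, best_perm = err, perm
    assert best_perm is not None
    return FiducialSet(
        labels=tuple(best_perm),
        positions_src=det,
        positions_dst=liv[list(best_perm)],
        frame_src=frame_src,
        frame_dst=frame_dst,
    )
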