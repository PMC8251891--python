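"""Rigid-body transform algebra and tracked-tool pose representations.

All world coordinates are millimetres in an LPS axis convention; the
electromagnetic (EM) tracker frame is the root world frame of the navigation
system.  Transforms follow the column-vector convention ``y = R @ x + t`` and
``compose(A, B)`` means "apply B first, then A".  Quaternions are stored
scalar-first ``(w, x, y, z)``.

Every transform carries mandatory ``frame_from`` / ``frame_to`` labels that
are checked at composition time: the navigation pipeline chains at least five
frames (MRI, CT, CBCT, EM, rib-relative) and a silent frame mix-up is the
classic way such chains go wrong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import FrameError

_UNIT_TOL = 1e-9


def _as_quat_wxyz(rotation: Rotation) -> np.ndarray:
    """scipy stores quaternions scalar-last; we expose scalar-first."""
    x, y, z, w = rotation.as_quat()
    q = np.array([w, x, y, z], dtype=float)
    # canonical sign: non-negative scalar part, deterministic across paths
    if q[0] < 0:
        q = -q
    return q


def _rotation_from_wxyz(q: Sequence[float]) -> Rotation:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError(f"quaternion must have 4 components, got shape {q.shape}")
    n = float(np.linalg.norm(q))
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm {n} is not 1 within 1e-6")
    w, x, y, z = q / n
    return Rotation.from_quat([x, y, z, w])


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping points between two named frames.

    Parameters
    ----------
    rotation : unit quaternion, scalar-first ``(w, x, y, z)``
    translation : 3-vector, mm
    frame_from, frame_to : coordinate-frame labels
    """

    rotation: np.ndarray
    translation: np.ndarray
    frame_from: str
    frame_to: str

    def __post_init__(self):
        rot = _rotation_from_wxyz(self.rotation)
        object.__setattr__(self, "rotation", _as_quat_wxyz(rot))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)
        if not self.frame_from or not self.frame_to:
            raise FrameError("frame_from and frame_to labels are mandatory")

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls, frame: str) -> "RigidTransform":
        return cls(np.array([1.0, 0, 0, 0]), np.zeros(3), frame, frame)

    @classmethod
    def from_rotation(
        cls, rotation: Rotation, translation, frame_from: str, frame_to: str
    ) -> "RigidTransform":
        return cls(_as_quat_wxyz(rotation), np.asarray(translation, float), frame_from, frame_to)

    @classmethod
    def from_matrix(cls, matrix, frame_from: str, frame_to: str) -> "RigidTransform":
        """Build from a 4x4 (or 3x4) homogeneous matrix; R must be a proper rotation."""
        m = np.asarray(matrix, dtype=float)
        if m.shape == (4, 4):
            if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
                raise ValueError("last row of a homogeneous rigid matrix must be [0,0,0,1]")
        elif m.shape != (3, 4):
            raise ValueError(f"expected 4x4 or 3x4 matrix, got {m.shape}")
        r = m[:3, :3]
        if abs(np.linalg.det(r) - 1.0) > 1e-6 or not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation block is not orthonormal with determinant +1")
        return cls.from_rotation(Rotation.from_matrix(r), m[:3, 3], frame_from, frame_to)

    # -- views ---------------------------------------------------------------

    @property
    def scipy_rotation(self) -> Rotation:
        return _rotation_from_wxyz(self.rotation)

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (column-vector convention)."""
        m = np.eye(4)
        m[:3, :3] = self.scipy_rotation.as_matrix()
        m[:3, 3] = self.translation
        return m

    @property
    def rotation_matrix(self) -> np.ndarray:
        return self.scipy_rotation.as_matrix()

    # -- algebra -------------------------------------------------------------

    def apply(self, points) -> np.ndarray:
        """Map points (N,3) or (3,) from ``frame_from`` into ``frame_to``."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation_matrix.T + self.translation
        return out[0] if single else out

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """``self ∘ inner``: apply ``inner`` first, then ``self``."""
        if inner.frame_to != self.frame_from:
            raise FrameError(
                f"cannot compose: inner maps to '{inner.frame_to}' but outer "
                f"expects '{self.frame_from}'"
            )
        rot = self.scipy_rotation * inner.scipy_rotation
        t = self.apply(inner.translation)
        return RigidTransform.from_rotation(rot, t, inner.frame_from, self.frame_to)

    def __matmul__(self, inner: "RigidTransform") -> "RigidTransform":
        return self.compose(inner)

    def invert(self) -> "RigidTransform":
        rot_inv = self.scipy_rotation.inv()
        t_inv = -rot_inv.apply(self.translation)
        return RigidTransform.from_rotation(rot_inv, t_inv, self.frame_to, self.frame_from)

    # -- diagnostics ---------------------------------------------------------

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        return float(np.degrees(self.scipy_rotation.magnitude()))

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    def is_identity(self, atol: float = _UNIT_TOL) -> bool:
        return self.scipy_rotation.magnitude() < atol and self.translation_norm() < atol

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        w, x, y, z = self.rotation
        tx, ty, tz = self.translation
        return (
            f"RigidTransform({self.frame_from}->{self.frame_to}, "
            f"q=[{w:.4f},{x:.4f},{y:.4f},{z:.4f}], t=[{tx:.2f},{ty:.2f},{tz:.2f}] mm)"
        )


# Functional aliases matching the operation names used throughout the docs.
def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    return outer.compose(inner)


def invert(transform: RigidTransform) -> RigidTransform:
    return transform.invert()


def apply(transform: RigidTransform, points) -> np.ndarray:
    return transform.apply(points)


def random_rigid_transform(
    rng: np.random.Generator,
    frame_from: str,
    frame_to: str,
    max_translation: float = 100.0,
    max_angle_deg: float = 180.0,
) -> RigidTransform:
    """Random rotation (axis uniform on the sphere, angle uniform up to the cap)
    + uniform translation in a cube."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0, max_angle_deg))
    rot = Rotation.from_rotvec(axis * angle)
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform.from_rotation(rot, t, frame_from, frame_to)


@dataclass(frozen=True)
class PoseSample:
    """One timestamped EM sensor reading.

    6-DoF sensors report full pose (position + orientation quaternion);
    5-DoF sensors report position + a unit axis direction (roll unobservable).
    """

    timestamp: float
    tool_id: str
    position: np.ndarray
    orientation: np.ndarray
    dof: int

    def __post_init__(self):
        p = np.asarray(self.position, dtype=float).reshape(3)
        object.__setattr__(self, "position", p)
        o = np.asarray(self.orientation, dtype=float)
        if self.dof == 6:
            if o.shape != (4,):
                raise ValueError("6-DoF pose requires a quaternion orientation")
            o = _as_quat_wxyz(_rotation_from_wxyz(o))
        elif self.dof == 5:
            if o.shape != (3,):
                raise ValueError("5-DoF pose requires a unit direction 3-vector")
            n = float(np.linalg.norm(o))
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"direction norm {n} is not 1 within 1e-6")
            o = o / n
        else:
            raise ValueError(f"dof must be 5 or 6, got {self.dof}")
        object.__setattr__(self, "orientation", o)

    def pose(self, frame: str = "em") -> RigidTransform:
        """The sensor's rigid pose: sensor-local frame -> tracker frame.

        Only defined for 6-DoF sensors; a 5-DoF sensor's roll is unobservable.
        """
        if self.dof != 6:
            raise ValueError(f"tool '{self.tool_id}' is 5-DoF: full pose undefined (no roll)")
        return RigidTransform(self.orientation, self.position, f"{self.tool_id}_local", frame)


def validate_stream(samples: Iterable[PoseSample]) -> None:
    """Check per-tool timestamp monotonicity (non-decreasing)."""
    last: dict[str, float] = {}
    for i, s in enumerate(samples):
        prev = last.get(s.tool_id)
        if prev is not None and s.timestamp < prev:
            raise ValueError(
                f"sample {i}: timestamp {s.timestamp} for tool '{s.tool_id}' "
                f"decreases (previous {prev})"
            )
        last[s.tool_id] = s.timestamp
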