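"""3-D scalar volume container with physical-space metadata.

``VolumeImage`` wraps a numpy voxel array indexed ``[i, j, k]`` (fastest
index = x) together with spacing, origin and a direction matrix, using the
ITK/LPS conventions: the world coordinate of voxel index ``i`` is
``origin + direction @ (spacing * i)``, 0-based, voxel-center.  Conversion to
and from SimpleITK images is lossless and is how volumes reach the
registration framework and disk formats (NIfTI, MetaImage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk


@dataclass
class VolumeImage:
    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame: str = "world"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    # -- geometry ------------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def index_to_world(self, indices) -> np.ndarray:
        """Continuous voxel indices (N,3) -> world mm (voxel-center convention)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        out = idx * self.spacing @ self.direction.T + self.origin
        return out[0] if np.asarray(indices).ndim == 1 else out

    def world_to_index(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.direction / self.spacing
        return out[0] if np.asarray(points).ndim == 1 else out

    def world_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World x/y/z coordinates of every voxel center, each shaped like ``voxels``.

        Only valid (and only needed) for axis-aligned volumes; rendering uses it
        to evaluate analytic tissue shapes on the grid.
        """
        if not np.allclose(self.direction, np.eye(3)):
            raise ValueError("world_grid requires an identity direction matrix")
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    # -- SimpleITK bridge ------------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.T))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, frame: str = "world") -> "VolumeImage":
        arr = sitk.GetArrayFromImage(img).T  # sitk returns [z,y,x]
        return cls(
            voxels=arr,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            direction=np.array(img.GetDirection()).reshape(3, 3),
            frame=frame,
        )

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        """Same grid, new voxel data."""
        return VolumeImage(voxels, self.spacing.copy(), self.origin.copy(),
                           self.direction.copy(), self.frame)
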