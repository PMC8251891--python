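"""Synthetic phantom: ground-truth surgical scenes, deformation and EM streams.

The generator emulates the intraoperative scene of EM-navigated open liver
surgery: a liver (ellipsoid) with tumor(s) and vessels, a rib cage, four
surgical clips on the liver surface near the target tumor, three external
patient trackers (two disc-shaped 5-DoF sensors each) on the chest wall, and
one 6-DoF EM sensor on the liver surface close to the tumor.  Everything is
generated deterministically from ``(config, seed)`` and every landmark's true
world position stays queryable through any deformation — which is what makes
target-registration-error profiling possible at all (a clinical system can
never measure TRE densely; the phantom can).

Geometry is carried twice, consistently: as analytic primitives (used by the
volume renderer and by the deformation ground truth) and as triangle meshes
built from those primitives (used by distance queries and file export).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .geometry import PoseSample, RigidTransform

# ---------------------------------------------------------------------------
# Analytic primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    center: np.ndarray
    semiaxes: np.ndarray
    # rotation kept implicit: scene-level transforms move the whole primitive
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def _local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.center) @ self.rotation

    def contains(self, points: np.ndarray) -> np.ndarray:
        q = self._local(points) / self.semiaxes
        return np.sum(q**2, axis=-1) <= 1.0

    def surface_point(self, direction: np.ndarray) -> np.ndarray:
        """Exact intersection of a ray from the center with the surface."""
        d = self.rotation.T @ (np.asarray(direction, float) / np.linalg.norm(direction))
        scale = 1.0 / np.sqrt(np.sum((d / self.semiaxes) ** 2))
        return self.center + self.rotation @ (d * scale)

    def transformed(self, t: RigidTransform) -> "Ellipsoid":
        return Ellipsoid(t.apply(self.center), self.semiaxes.copy(),
                         t.rotation_matrix @ self.rotation)

    def bounds(self) -> np.ndarray:
        r = np.abs(self.rotation) @ self.semiaxes
        return np.array([self.center - r, self.center + r])


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(points) - self.center, axis=-1) <= self.radius

    def transformed(self, t: RigidTransform) -> "Sphere":
        return Sphere(t.apply(self.center), self.radius)

    def displaced(self, fn) -> "Sphere":
        return Sphere(fn(self.center[None])[0], self.radius)

    def bounds(self) -> np.ndarray:
        return np.array([self.center - self.radius, self.center + self.radius])


@dataclass(frozen=True)
class Capsule:
    """Cylinder with hemispherical caps between two endpoints (vessels, ribs, clips)."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float

    def distance(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d = self.p1 - self.p0
        length2 = float(d @ d)
        if length2 < 1e-12:
            return np.linalg.norm(p - self.p0, axis=-1)
        u = np.clip((p - self.p0) @ d / length2, 0.0, 1.0)
        foot = self.p0 + u[:, None] * d
        return np.linalg.norm(p - foot, axis=-1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.distance(points) <= self.radius

    def transformed(self, t: RigidTransform) -> "Capsule":
        return Capsule(t.apply(self.p0), t.apply(self.p1), self.radius)

    def displaced(self, fn) -> "Capsule":
        ends = fn(np.vstack([self.p0, self.p1]))
        return Capsule(ends[0], ends[1], self.radius)

    def bounds(self) -> np.ndarray:
        lo = np.minimum(self.p0, self.p1) - self.radius
        hi = np.maximum(self.p0, self.p1) + self.radius
        return np.array([lo, hi])


@dataclass(frozen=True)
class Disc:
    """Flat metal cylinder (tracker sensor disc): center, unit normal, radius, thickness."""

    center: np.ndarray
    normal: np.ndarray
    radius: float
    thickness: float

    def sdf(self, points: np.ndarray) -> np.ndarray:
        """Signed distance (negative inside); exact for a finite cylinder."""
        p = np.atleast_2d(points) - self.center
        axial = p @ self.normal
        radial = np.linalg.norm(p - np.outer(axial, self.normal), axis=-1)
        da = np.abs(axial) - self.thickness / 2.0
        dr = radial - self.radius
        outside = np.sqrt(np.maximum(da, 0) ** 2 + np.maximum(dr, 0) ** 2)
        inside = np.minimum(np.maximum(da, dr), 0.0)
        return outside + inside

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.sdf(points) <= 0.0

    def transformed(self, t: RigidTransform) -> "Disc":
        return Disc(t.apply(self.center), t.rotation_matrix @ self.normal,
                    self.radius, self.thickness)

    def bounds(self) -> np.ndarray:
        r = self.radius + self.thickness  # loose, cheap
        return np.array([self.center - r, self.center + r])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SceneConfig:
    """Study conditions of the phantom (all lengths in mm).

    Defaults describe one adult-scale scene: liver-sized ellipsoid, a single
    1.2-cm target tumor near the anterior surface, a rib cage that the
    truncated-FOV CBCT can still image, four clips around the tumor and three
    chest trackers whose paired disc sensors sit 20 mm apart.
    """

    liver_semiaxes: tuple = (120.0, 80.0, 60.0)
    liver_center: tuple = (0.0, 0.0, 0.0)
    torso_semiaxes: tuple = (165.0, 135.0, 240.0)
    n_tumors: int = 1
    tumor_radius: float = 12.0
    n_vessels: int = 3
    vessel_radius: float = 4.0
    rib_levels: tuple = (-80.0, -40.0, 0.0, 40.0, 80.0)
    rib_arc_radius: float = 140.0
    rib_tube_radius: float = 5.0
    include_spine: bool = True  # vertebral column + sternum anchor the bone anatomy
    vertebra_radius: float = 14.0
    sternum_radius: float = 7.0
    n_clips: int = 4
    clip_radius: float = 1.0
    clip_length: float = 3.0
    tracker_surface_radius: float = 155.0
    disc_pairing_distance: float = 20.0
    disc_radius: float = 4.0
    disc_thickness: float = 2.0
    sensor_max_tumor_distance: float = 50.0

    def validate(self) -> None:
        a = np.asarray(self.liver_semiaxes, float)
        if np.any(a <= 0):
            raise ConfigError(f"liver semi-axes must be positive, got {a}")
        if self.n_tumors < 0:
            raise ConfigError("n_tumors must be >= 0")
        if self.n_tumors and self.tumor_radius >= 0.9 * a.min():
            raise ConfigError(
                f"tumor radius {self.tumor_radius} mm cannot fit inside liver "
                f"semi-axes {tuple(a)} with margin"
            )
        if self.n_clips != 4:
            raise ConfigError(f"the clip protocol uses 4 surgical clips, got {self.n_clips}")
        if self.disc_pairing_distance <= 2 * self.disc_radius:
            raise ConfigError("disc pairing distance must exceed one disc diameter")


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackerDiscs:
    """Six disc sensors grouped into 3 patient trackers (pairs by index)."""

    centers: np.ndarray  # (6,3)
    normals: np.ndarray  # (6,3), unit
    pairs: tuple = ((0, 1), (2, 3), (4, 5))
    pairing_distance: float = 20.0


@dataclass(frozen=True)
class CorrespondenceMap:
    """Correspondence between a scene state and its reference state.

    ``forward`` maps reference-state points to their current true positions;
    for a freshly generated scene it is the identity.
    """

    forward: Callable[[np.ndarray], np.ndarray]
    description: str = "identity"

    @classmethod
    def identity(cls) -> "CorrespondenceMap":
        return cls(forward=lambda pts: np.array(pts, dtype=float, copy=True))


@dataclass(frozen=True)
class PhantomScene:
    config: SceneConfig
    frame: str
    liver_mesh: trimesh.Trimesh
    tumor_meshes: list
    vessel_meshes: list
    rib_meshes: list
    clip_positions: np.ndarray  # (4,3)
    tracker_discs: TrackerDiscs
    liver_sensor_pose: RigidTransform  # liver_sensor_local -> scene frame
    primitives: dict
    reference_map: CorrespondenceMap

    # -- ground-truth queries ------------------------------------------------

    @property
    def tumor_centers(self) -> np.ndarray:
        return np.array([s.center for s in self.primitives["tumors"]]).reshape(-1, 3)

    @property
    def sensor_position(self) -> np.ndarray:
        return self.liver_sensor_pose.translation

    def landmarks(self) -> dict:
        """Named true world positions of every discrete landmark."""
        marks = {f"clip_{i}": p for i, p in enumerate(self.clip_positions)}
        for i, c in enumerate(self.tumor_centers):
            marks[f"tumor_{i}_center"] = c
        for i, c in enumerate(self.tracker_discs.centers):
            marks[f"disc_{i}"] = c
        marks["liver_sensor"] = self.sensor_position
        return marks

    def liver_sample_points(self, n: int, seed: int) -> np.ndarray:
        """Deterministic quasi-uniform sample of points inside the liver."""
        liver: Ellipsoid = self.primitives["liver"]
        rng = np.random.default_rng(seed)
        pts = []
        while len(pts) < n:
            cand = rng.uniform(-1, 1, size=(4 * n, 3)) * liver.semiaxes
            cand = cand[np.sum((cand / liver.semiaxes) ** 2, axis=1) <= 1.0]
            pts.extend(liver.center + cand @ liver.rotation.T)
        return np.array(pts[:n])

    # -- rigid motion of the whole scene ------------------------------------

    def transformed(self, t: RigidTransform) -> "PhantomScene":
        """Apply a rigid transform to every structure (frame change / global motion)."""
        prim = {
            "torso": self.primitives["torso"].transformed(t),
            "liver": self.primitives["liver"].transformed(t),
            "tumors": [s.transformed(t) for s in self.primitives["tumors"]],
            "vessels": [c.transformed(t) for c in self.primitives["vessels"]],
            "ribs": [[c.transformed(t) for c in rib] for rib in self.primitives["ribs"]],
            "clips": [c.transformed(t) for c in self.primitives["clips"]],
            "discs": [d.transformed(t) for d in self.primitives["discs"]],
        }
        fwd_old = self.reference_map.forward
        return PhantomScene(
            config=self.config,
            frame=t.frame_to,
            liver_mesh=_transform_mesh(self.liver_mesh, t),
            tumor_meshes=[_transform_mesh(m, t) for m in self.tumor_meshes],
            vessel_meshes=[_transform_mesh(m, t) for m in self.vessel_meshes],
            rib_meshes=[_transform_mesh(m, t) for m in self.rib_meshes],
            clip_positions=t.apply(self.clip_positions),
            tracker_discs=TrackerDiscs(
                t.apply(self.tracker_discs.centers),
                self.tracker_discs.normals @ t.rotation_matrix.T,
                self.tracker_discs.pairs,
                self.tracker_discs.pairing_distance,
            ),
            liver_sensor_pose=t @ self.liver_sensor_pose,
            primitives=prim,
            reference_map=CorrespondenceMap(
                forward=lambda pts: t.apply(fwd_old(pts)),
                description=f"{self.reference_map.description} + rigid",
            ),
        )


def _transform_mesh(mesh: trimesh.Trimesh, t: RigidTransform) -> trimesh.Trimesh:
    out = mesh.copy()
    out.apply_transform(t.as_matrix())
    return out


def _mesh_from_capsules(capsules: Sequence[Capsule], sections: int = 12) -> trimesh.Trimesh:
    parts = []
    for c in capsules:
        d = c.p1 - c.p0
        h = float(np.linalg.norm(d))
        seg = trimesh.creation.capsule(height=max(h, 1e-6), radius=c.radius, count=[sections, sections])
        # capsule axis is +z centered at origin; align to the segment
        z = np.array([0.0, 0.0, 1.0])
        axis = d / h if h > 1e-9 else z
        rot = trimesh.geometry.align_vectors(z, axis)
        seg.apply_transform(rot)
        seg.apply_translation((c.p0 + c.p1) / 2.0)
        parts.append(seg)
    return trimesh.util.concatenate(parts)


def _ellipsoid_mesh(e: Ellipsoid, subdivisions: int = 3) -> trimesh.Trimesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions)
    m.vertices = m.vertices * e.semiaxes @ e.rotation.T + e.center
    return m


def _sphere_mesh(s: Sphere, subdivisions: int = 3) -> trimesh.Trimesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=s.radius)
    m.apply_translation(s.center)
    return m


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(n, t1)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------


def generate_scene(config: Optional[SceneConfig] = None, seed: int = 0,
                   frame: str = "world") -> PhantomScene:
    """Build a ground-truth scene, deterministic per ``(config, seed)``."""
    config = config or SceneConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    liver = Ellipsoid(np.asarray(config.liver_center, float),
                      np.asarray(config.liver_semiaxes, float))
    torso = Ellipsoid(liver.center + np.array([0.0, 25.0, 0.0]),
                      np.asarray(config.torso_semiaxes, float))

    # tumors: first one anterior near the surface (the navigation target),
    # the rest placed inward with a containment margin
    tumors: list[Sphere] = []
    for i in range(config.n_tumors):
        if i == 0:
            direction = np.array([0.35, -0.85, 0.25]) + rng.normal(0, 0.05, 3)
        else:
            direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # ellipsoidal fraction: close to the wall for the target, deeper otherwise
        frac = 0.60 if i == 0 else rng.uniform(0.2, 0.5)
        surf = liver.surface_point(direction)
        center = liver.center + frac * (surf - liver.center)
        tumors.append(Sphere(center, config.tumor_radius))
        margin = np.sqrt(np.sum(((center - liver.center) / liver.semiaxes) ** 2))
        if margin + config.tumor_radius / liver.semiaxes.min() > 0.98:
            raise ConfigError("tumor does not fit inside the liver with margin")

    # vessels: chords between interior points
    vessels: list[Capsule] = []
    for _ in range(config.n_vessels):
        ends = []
        for _ in range(2):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ends.append(liver.center + 0.7 * rng.uniform(0.4, 1.0)
                        * (liver.surface_point(d) - liver.center))
        vessels.append(Capsule(ends[0], ends[1], config.vessel_radius))

    # ribs: elliptical arcs in axial planes, anterior-lateral span
    ribs: list[list[Capsule]] = []
    thetas = np.linspace(np.radians(-110), np.radians(110), 16)
    for z in config.rib_levels:
        pts = np.column_stack([
            1.1 * config.rib_arc_radius * np.sin(thetas),
            -config.rib_arc_radius * np.cos(thetas) + 25.0,
            np.full_like(thetas, z),
        ])
        ribs.append([Capsule(pts[i], pts[i + 1], config.rib_tube_radius)
                     for i in range(len(pts) - 1)])
    if config.include_spine:
        # vertebral bodies (stacked, with inter-vertebral gaps) and the sternum:
        # without them the circular rib arcs leave axial rotation and axial
        # shift of the bone anatomy almost unconstrained
        spine_y = config.rib_arc_radius * 0.82 + 25.0
        for zc in np.arange(-96.0, 97.0, 28.0):
            ribs.append([Capsule(np.array([0.0, spine_y, zc - 9.0]),
                                 np.array([0.0, spine_y, zc + 9.0]),
                                 config.vertebra_radius)])
        sternum_y = -(config.rib_arc_radius * 0.88) + 25.0
        ribs.append([Capsule(np.array([0.0, sternum_y, -70.0]),
                             np.array([0.0, sternum_y, 70.0]),
                             config.sternum_radius)])

    # clips: on the liver surface, clustered around the target tumor direction
    # clips ring the target at ~90 degree spacing (they mark the planned
    # resection margin around the tumor, not a single spot)
    target_dir = (tumors[0].center - liver.center) if tumors else np.array([0.0, -1.0, 0.0])
    u = target_dir / np.linalg.norm(target_dir)
    tu1, tu2 = _tangent_basis(u)
    clips: list[Capsule] = []
    clip_positions = []
    for i in range(config.n_clips):
        phi = 2 * np.pi * i / config.n_clips + rng.normal(0, 0.15)
        tilt = np.radians(22.0 + rng.normal(0, 3.0))
        direction = np.cos(tilt) * u + np.sin(tilt) * (np.cos(phi) * tu1 + np.sin(phi) * tu2)
        p = liver.surface_point(direction)
        t1, _ = _tangent_basis(p - liver.center)
        half = 0.5 * config.clip_length * t1
        clips.append(Capsule(p - half, p + half, config.clip_radius))
        clip_positions.append(p)
    clip_positions = np.array(clip_positions)

    # liver 6-DoF sensor: surface point nearest the target tumor
    sensor_pos = liver.surface_point(target_dir)
    outward = sensor_pos - liver.center
    t1, t2 = _tangent_basis(outward)
    n = outward / np.linalg.norm(outward)
    rot = Rotation.from_matrix(np.column_stack([t1, t2, n]))
    sensor_pose = RigidTransform.from_rotation(rot, sensor_pos, "liver_sensor_local", frame)
    if tumors:
        dist = np.linalg.norm(sensor_pos - tumors[0].center) - tumors[0].radius
        if dist > config.sensor_max_tumor_distance:
            raise ConfigError(
                f"liver sensor is {dist:.1f} mm from the target tumor surface "
                f"(limit {config.sensor_max_tumor_distance} mm)"
            )

    # patient trackers: 3 on the chest wall, 2 discs each, paired along z.
    # deliberately irregular placement: a symmetric layout makes the 6-point
    # correspondence ambiguous (a flipped assignment registers just as well)
    disc_centers, disc_normals = [], []
    for theta_deg, z in ((-70.0, -55.0), (-10.0, 20.0), (55.0, 65.0)):
        th = np.radians(theta_deg)
        base = np.array([
            1.1 * config.tracker_surface_radius * np.sin(th),
            -config.tracker_surface_radius * np.cos(th) + 25.0,
            z,
        ])
        normal = np.array([1.1 * np.sin(th), -np.cos(th), 0.0])
        normal /= np.linalg.norm(normal)
        offset = np.array([0.0, 0.0, config.disc_pairing_distance / 2.0])
        for sgn in (-1.0, 1.0):
            disc_centers.append(base + sgn * offset)
            disc_normals.append(normal)
    discs = [Disc(c, nrm, config.disc_radius, config.disc_thickness)
             for c, nrm in zip(disc_centers, disc_normals)]
    tracker = TrackerDiscs(np.array(disc_centers), np.array(disc_normals),
                           pairing_distance=config.disc_pairing_distance)

    primitives = {
        "torso": torso, "liver": liver, "tumors": tumors, "vessels": vessels,
        "ribs": ribs, "clips": clips, "discs": discs,
    }
    return PhantomScene(
        config=config,
        frame=frame,
        liver_mesh=_ellipsoid_mesh(liver),
        tumor_meshes=[_sphere_mesh(s) for s in tumors],
        vessel_meshes=[_mesh_from_capsules([c]) for c in vessels],
        rib_meshes=[_mesh_from_capsules(rib) for rib in ribs],
        clip_positions=clip_positions,
        tracker_discs=tracker,
        liver_sensor_pose=sensor_pose,
        primitives=primitives,
        reference_map=CorrespondenceMap.identity(),
    )


# ---------------------------------------------------------------------------
# Deformation model
# ---------------------------------------------------------------------------


def _smoothstep(d: np.ndarray, r0: float, r1: float) -> np.ndarray:
    """C1 ramp: 0 for d <= r0, 1 for d >= r1, cubic Hermite between."""
    u = np.clip((d - r0) / (r1 - r0), 0.0, 1.0)
    return 3 * u**2 - 2 * u**3


@dataclass(frozen=True)
class GaussianDisplacementField:
    """Sum of Gaussian-kernel displacements with a rigid core around the sensor.

    ``u(x) = s(|x - x_sensor|) * sum_k v_k exp(-|x - c_k|^2 / (2 L^2))`` where
    the attenuation ``s`` is a C1 smoothstep that is exactly zero inside
    ``core_radius`` and reaches 1 at ``2.5 * core_radius``.  This realizes the
    local-rigidity premise of single-sensor tracking: tissue near the sensor
    moves rigidly with it; tissue far away does not.
    """

    centers: np.ndarray  # (K,3) kernel centers, reference frame
    vectors: np.ndarray  # (K,3) kernel displacement vectors, mm
    length_scale: float  # mm
    core_radius: float  # mm
    sensor_position: np.ndarray  # reference frame

    def raw(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        u = np.zeros_like(p)
        for c, v in zip(self.centers, self.vectors):
            w = np.exp(-np.sum((p - c) ** 2, axis=1) / (2 * self.length_scale**2))
            u += np.outer(w, v)
        return u

    def displacement(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d = np.linalg.norm(p - self.sensor_position, axis=1)
        s = _smoothstep(d, self.core_radius, 2.5 * self.core_radius)
        return self.raw(p) * s[:, None]

    @property
    def magnitude(self) -> float:
        return float(np.max(np.linalg.norm(self.vectors, axis=1)))


@dataclass(frozen=True)
class DeformationModel:
    """Trajectory of the scene: global rigid motion + breathing + local field.

    * ``global_trajectory(t)`` moves the whole body (ribs included) rigidly.
    * breathing is a sinusoidal cranio-caudal translation of the liver only
      (amplitude vector, mm; period, s); the clinical system snapshots at
      breath-hold, which the simulator reproduces by sampling at a fixed phase.
    * ``local_field`` is manipulation-induced liver deformation (liver
      structures only), attenuated to zero in the rigid core at the sensor.
    """

    global_trajectory: Callable[[float], RigidTransform] = None
    breathing_amplitude: np.ndarray = field(default_factory=lambda: np.zeros(3))
    breathing_period: float = 4.0
    local_field: Optional[GaussianDisplacementField] = None
    # optional ramp for the manipulation field, e.g. zero at the CBCT snapshot
    field_envelope: Optional[Callable[[float], float]] = None

    def global_at(self, t: float, frame: str) -> RigidTransform:
        if self.global_trajectory is None:
            return RigidTransform.identity(frame)
        return self.global_trajectory(t)

    def breathing_at(self, t: float) -> np.ndarray:
        amp = np.asarray(self.breathing_amplitude, float)
        if not np.any(amp):
            return np.zeros(3)
        return amp * np.sin(2 * np.pi * t / self.breathing_period)


def static_model() -> DeformationModel:
    return DeformationModel()


def default_manipulation_field(
    scene: PhantomScene, magnitude: float = 10.0, length_scale: float = 100.0,
    core_radius: float = 30.0, n_kernels: int = 3, seed: int = 0,
) -> GaussianDisplacementField:
    """Manipulation field with kernels on the liver lobe far from the sensor.

    Surgical manipulation (packing, retraction) acts on the organ away from
    the tracked target zone; kernels therefore sit beyond the liver center as
    seen from the sensor, so displacement grows with distance from the sensor.
    """
    rng = np.random.default_rng(seed)
    liver: Ellipsoid = scene.primitives["liver"]
    sensor = scene.sensor_position
    away = liver.center - sensor
    away /= np.linalg.norm(away)
    centers, vectors = [], []
    for _ in range(n_kernels):
        jitter = rng.normal(0, 0.2, 3)
        direction = away + jitter
        direction /= np.linalg.norm(direction)
        surf = liver.surface_point(direction)
        centers.append(liver.center + 0.85 * (surf - liver.center))
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        vectors.append(v * magnitude)
    return GaussianDisplacementField(
        centers=np.array(centers), vectors=np.array(vectors),
        length_scale=length_scale, core_radius=core_radius,
        sensor_position=np.array(sensor, copy=True),
    )


def apply_deformation(scene: PhantomScene, model: DeformationModel,
                      time: float) -> PhantomScene:
    """Deform ``scene`` (assumed to be a reference state) to its state at ``time``.

    Ribs and chest trackers move only with the global rigid trajectory; liver
    structures additionally receive breathing translation and the local field.
    The returned scene's ``reference_map.forward`` maps reference points to
    their true deformed positions, and the liver-sensor pose follows the rigid
    part of the motion (its position includes the — by construction negligible
    — local field at the sensor).
    """
    g = model.global_at(time, scene.frame)
    if g.frame_from != scene.frame:
        raise ConfigError(
            f"global trajectory maps from '{g.frame_from}' but scene is in '{scene.frame}'")
    breath = model.breathing_at(time)
    rot_g = g.rotation_matrix
    field_ = model.local_field
    envelope = 1.0 if model.field_envelope is None else float(model.field_envelope(time))

    def liver_map(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        out = g.apply(pts) + breath
        if field_ is not None and envelope != 0.0:
            out = out + envelope * field_.displacement(pts) @ rot_g.T
        return out

    def rib_map(pts: np.ndarray) -> np.ndarray:
        return g.apply(np.atleast_2d(np.asarray(pts, float)))

    def deform_mesh(mesh: trimesh.Trimesh, fn) -> trimesh.Trimesh:
        out = mesh.copy()
        out.vertices = fn(out.vertices)
        return out

    prim = scene.primitives
    new_prim = {
        "torso": prim["torso"].transformed(g),
        "liver": prim["liver"].transformed(g),  # analytic shell: rigid part only
        "tumors": [s.displaced(liver_map) for s in prim["tumors"]],
        "vessels": [c.displaced(liver_map) for c in prim["vessels"]],
        "ribs": [[c.transformed(g) for c in rib] for rib in prim["ribs"]],
        "clips": [c.displaced(liver_map) for c in prim["clips"]],
        "discs": [d.transformed(g) for d in prim["discs"]],
    }
    # liver analytic primitive also gets the breathing offset
    liver_e: Ellipsoid = new_prim["liver"]
    new_prim["liver"] = Ellipsoid(liver_e.center + breath, liver_e.semiaxes, liver_e.rotation)

    sensor_ref = scene.liver_sensor_pose
    sensor_pos = liver_map(sensor_ref.translation[None])[0]
    sensor_rot = Rotation.from_matrix(rot_g @ sensor_ref.rotation_matrix)
    sensor_pose = RigidTransform.from_rotation(
        sensor_rot, sensor_pos, sensor_ref.frame_from, g.frame_to)

    fwd_old = scene.reference_map.forward
    return PhantomScene(
        config=scene.config,
        frame=g.frame_to,
        liver_mesh=deform_mesh(scene.liver_mesh, liver_map),
        tumor_meshes=[deform_mesh(m, liver_map) for m in scene.tumor_meshes],
        vessel_meshes=[deform_mesh(m, liver_map) for m in scene.vessel_meshes],
        rib_meshes=[deform_mesh(m, rib_map) for m in scene.rib_meshes],
        clip_positions=liver_map(scene.clip_positions),
        tracker_discs=TrackerDiscs(
            rib_map(scene.tracker_discs.centers),
            scene.tracker_discs.normals @ rot_g.T,
            scene.tracker_discs.pairs,
            scene.tracker_discs.pairing_distance,
        ),
        liver_sensor_pose=sensor_pose,
        primitives=new_prim,
        reference_map=CorrespondenceMap(
            forward=lambda pts: liver_map(fwd_old(pts)),
            description=f"deformed(t={time})",
        ),
    )


# ---------------------------------------------------------------------------
# EM measurement simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EMNoiseModel:
    """Additive EM measurement noise; sigmas per sample, not per axis RMS."""

    sigma_pos: float = 0.5  # mm per axis
    sigma_rot: float = 0.3  # degrees
    seed: int = 0

    def __post_init__(self):
        if self.sigma_pos < 0 or self.sigma_rot < 0:
            raise ConfigError("noise sigmas must be non-negative")


TRACKER_TOOL_IDS = tuple(f"tracker_disc_{i}" for i in range(6))


def simulate_em_stream(
    scene_trajectory: Callable[[float], PhantomScene],
    noise: EMNoiseModel,
    rate: float = 10.0,
    duration: float = 1.0,
    world_to_em: Optional[RigidTransform] = None,
    pointer_trajectory: Optional[Callable[[float], RigidTransform]] = None,
) -> list[PoseSample]:
    """Sample noisy EM readings of every tool at the given frame rate.

    Tools: the liver 6-DoF sensor, the six 5-DoF tracker disc sensors
    (position + disc normal; roll unobservable) and, when a trajectory is
    supplied, a 6-DoF surgical pointer.  With zero sigmas the stream equals
    ground truth exactly.
    """
    if rate <= 0:
        raise ConfigError(f"rate must be positive, got {rate}")
    rng = np.random.default_rng(noise.seed)
    n = int(round(rate * duration))
    samples: list[PoseSample] = []

    def noisy_pos(p: np.ndarray) -> np.ndarray:
        if noise.sigma_pos == 0:
            return p
        return p + rng.normal(0, noise.sigma_pos, 3)

    def noise_rotation() -> Rotation:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.normal(0, noise.sigma_rot))
        return Rotation.from_rotvec(axis * angle)

    for i in range(n):
        t = i / rate
        scene = scene_trajectory(t)
        to_em = world_to_em
        if to_em is None:
            to_em = RigidTransform.identity(scene.frame)
            to_em = RigidTransform(to_em.rotation, to_em.translation, scene.frame, "em")
        # liver 6-DoF sensor
        pose = to_em @ scene.liver_sensor_pose
        rot = pose.scipy_rotation
        if noise.sigma_rot > 0:
            rot = noise_rotation() * rot
        samples.append(PoseSample(t, "liver_sensor", noisy_pos(pose.translation),
                                  _wxyz(rot), 6))
        # tracker discs, 5-DoF
        centers = to_em.apply(scene.tracker_discs.centers)
        normals = scene.tracker_discs.normals @ to_em.rotation_matrix.T
        for k, tool in enumerate(TRACKER_TOOL_IDS):
            direction = normals[k]
            if noise.sigma_rot > 0:
                direction = noise_rotation().apply(direction)
            samples.append(PoseSample(t, tool, noisy_pos(centers[k]), direction, 5))
        # pointer
        if pointer_trajectory is not None:
            ptr = to_em @ pointer_trajectory(t)
            rot = ptr.scipy_rotation
            if noise.sigma_rot > 0:
                rot = noise_rotation() * rot
            samples.append(PoseSample(t, "pointer", noisy_pos(ptr.translation),
                                      _wxyz(rot), 6))
    return samples


def _wxyz(rot: Rotation) -> np.ndarray:
    x, y, z, w = rot.as_quat()
    return np.array([w, x, y, z])
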