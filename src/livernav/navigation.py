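"""Semi-rigid navigation core: registration chain, live tracking, guidance.

The chain brings the preoperative model into tracker space:
``model (MRI) --T1--> CBCT --T23--> EM``, with an optional ``T4`` linking the
preoperative CT (rib model) into the CBCT.  Live tracking approximates the
liver near its surface-mounted 6-DoF EM sensor as locally rigid: whatever
rigid motion the sensor pose undergoes relative to its snapshot at CBCT
acquisition is applied to the whole model.  Guidance validity is restricted
to a spherical "target navigation zone" (default radius 50 mm) around the
live sensor position; outputs outside it carry an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import trimesh

from .errors import CardinalityError, FrameError
from .fiducials import FiducialSet, register_points
from .meshdist import MeshDistanceQuery
from .geometry import PoseSample, RigidTransform

DEFAULT_ZONE_RADIUS = 50.0  # mm


def liver_tracking_transform(
    s_live: PoseSample, s_ref: PoseSample, translation_only: bool = False
) -> RigidTransform:
    """Rigid transform (EM frame) carrying the snapshot state to the live state.

    ``T = pose(S_live) o pose(S_ref)^-1``: any point rigidly attached to the
    sensor maps from its snapshot position to its live position.  The full
    6-DoF pose drives the transform; ``translation_only`` ablates rotation
    (pure displacement of the sensor location), which drops the lever-arm
    correction for points away from the sensor.
    """
    if s_live.dof != 6 or s_ref.dof != 6:
        raise ValueError("liver tracking requires 6-DoF poses (roll is unobservable at 5-DoF)")
    if s_live.tool_id != s_ref.tool_id:
        raise ValueError(
            f"pose samples from different tools: '{s_live.tool_id}' vs '{s_ref.tool_id}'")
    if translation_only:
        return RigidTransform(np.array([1.0, 0, 0, 0]),
                              s_live.position - s_ref.position, "em", "em")
    t = s_live.pose("em") @ s_ref.pose("em").invert()
    return RigidTransform(t.rotation, t.translation, "em", "em")


def smooth_stream(samples, alpha: float = 0.3) -> list[PoseSample]:
    """Optional exponential moving average over a per-tool pose stream.

    Off by default throughout the pipeline (the tracking model consumes raw
    samples); provided for replaying jittery recordings.  Positions are
    EMA-filtered per tool; 6-DoF orientations through normalized quaternion
    blending (hemisphere-aligned), 5-DoF directions by renormalized EMA.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    state: dict[str, PoseSample] = {}
    out: list[PoseSample] = []
    for s in samples:
        prev = state.get(s.tool_id)
        if prev is None:
            smoothed = s
        else:
            pos = alpha * s.position + (1 - alpha) * prev.position
            ori = np.asarray(s.orientation, float)
            prev_ori = np.asarray(prev.orientation, float)
            if s.dof == 6 and float(ori @ prev_ori) < 0:
                ori = -ori  # same hemisphere before blending
            blend = alpha * ori + (1 - alpha) * prev_ori
            blend /= np.linalg.norm(blend)
            smoothed = PoseSample(s.timestamp, s.tool_id, pos, blend, s.dof)
        state[s.tool_id] = smoothed
        out.append(smoothed)
    return out


@dataclass(frozen=True)
class RegistrationChain:
    """Validated transform chain from model space to EM tracker space."""

    t1: RigidTransform  # model (MRI) -> CBCT
    t23: RigidTransform  # CBCT -> EM
    s_ref: PoseSample  # liver 6-DoF sensor at the CBCT snapshot
    tracker_ref: np.ndarray  # (6,3) tracker sensor positions at snapshot, EM frame
    t4: Optional[RigidTransform] = None  # CT -> CBCT

    def __post_init__(self):
        object.__setattr__(self, "tracker_ref",
                           np.asarray(self.tracker_ref, float).reshape(6, 3))
        if self.t1.frame_to != self.t23.frame_from:
            raise FrameError(
                f"chain gap: T1 ends in '{self.t1.frame_to}' but T23 starts in "
                f"'{self.t23.frame_from}'")
        if self.t4 is not None and self.t4.frame_to != self.t23.frame_from:
            raise FrameError(
                f"chain gap: T4 ends in '{self.t4.frame_to}' but T23 starts in "
                f"'{self.t23.frame_from}'")
        if self.s_ref.dof != 6:
            raise ValueError("the liver reference pose must be 6-DoF")

    @property
    def model_frame(self) -> str:
        return self.t1.frame_from

    @property
    def static_model_to_em(self) -> RigidTransform:
        return self.t23 @ self.t1


def build_chain(
    t1: RigidTransform,
    t23: RigidTransform,
    s_ref: PoseSample,
    tracker_ref,
    t4: Optional[RigidTransform] = None,
) -> RegistrationChain:
    """Assemble and validate the registration chain (refuses frame gaps)."""
    return RegistrationChain(t1=t1, t23=t23, s_ref=s_ref, tracker_ref=tracker_ref, t4=t4)


@dataclass(frozen=True)
class NavigationState:
    """One guidance instant: the chain plus the live sensor (and pointer) poses."""

    chain: RegistrationChain
    s_live: PoseSample
    pointer_live: Optional[PoseSample] = None
    zone_radius: float = DEFAULT_ZONE_RADIUS
    translation_only: bool = False

    def __post_init__(self):
        if self.zone_radius <= 0:
            raise ValueError(f"zone radius must be positive, got {self.zone_radius}")

    @property
    def tracking_transform(self) -> RigidTransform:
        return liver_tracking_transform(self.s_live, self.chain.s_ref,
                                        self.translation_only)

    @property
    def model_to_em_live(self) -> RigidTransform:
        return self.tracking_transform @ self.chain.static_model_to_em

    @property
    def live_sensor_position(self) -> np.ndarray:
        return self.s_live.position


def locate_model(state: NavigationState, model_points) -> np.ndarray:
    """Map model-space points to their live EM-space positions.

    When the live pose equals the snapshot pose this reduces exactly to the
    static CBCT registration ``T23 o T1``.
    """
    return state.model_to_em_live.apply(np.asarray(model_points, float))


def rib_frame(tracker_live, chain: RegistrationChain) -> tuple[RigidTransform, float]:
    """Rigid rib-motion transform (snapshot -> live) from the six tracker sensors.

    Fitted by least-squares point registration of the six disc-sensor
    positions; returns (transform, FRE).  The liver's motion *relative to the
    ribs* is ``invert(rib) o liver_tracking_transform`` — the quantity a
    display anchored to the patient's body shows.
    """
    live = np.asarray(tracker_live, float).reshape(-1, 3)
    if live.shape != (6, 3):
        raise CardinalityError(f"expected 6 live tracker positions, got {live.shape[0]}")
    fids = FiducialSet(
        labels=tuple(range(6)),
        positions_src=chain.tracker_ref,
        positions_dst=live,
        frame_src="em",
        frame_dst="em",
    )
    return register_points(fids)


def liver_relative_to_ribs(state: NavigationState, tracker_live) -> RigidTransform:
    rib, _ = rib_frame(tracker_live, state.chain)
    return rib.invert() @ state.tracking_transform


def pointer_to_tumor_distance(
    pointer_tip, state: NavigationState, tumor_mesh_model: trimesh.Trimesh
) -> tuple[float, np.ndarray]:
    """Shortest distance (mm) from the pointer tip to the tracked tumor surface.

    The tumor mesh (model space) is carried to live EM space through the
    chain; distance is the exact point-to-triangle minimum over the surface
    (k-d-tree-pruned proximity query), clamped to 0 when the tip is inside
    the tumor.  Returns (distance, foot point on the surface) — the foot
    point is what the guidance display draws the ruler to.
    """
    if tumor_mesh_model.faces.shape[0] == 0:
        raise ValueError("tumor mesh has no faces")
    tip = np.asarray(pointer_tip, float).reshape(3)
    live = tumor_mesh_model.copy()
    live.apply_transform(state.model_to_em_live.as_matrix())
    query = MeshDistanceQuery(live)
    distance, feet = query.closest(tip[None])
    d = float(distance[0])
    if live.is_watertight and query.contains(tip[None])[0]:
        d = 0.0
    return d, feet[0]


def in_target_zone(point, state: NavigationState) -> tuple[bool, float]:
    """Whether a point lies in the target navigation zone; boundary is closed.

    Guidance (and accuracy claims) only apply within ``zone_radius`` of the
    live sensor; outside, the model is indicative visualization only.
    """
    d = float(np.linalg.norm(np.asarray(point, float) - state.live_sensor_position))
    return d <= state.zone_radius, d
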