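"""Semi-rigid tracking: chain validation, live tracking, guidance distances."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from livernav import (FrameError, NavigationState, PoseSample, RigidTransform,
                      build_chain, in_target_zone, liver_relative_to_ribs,
                      liver_tracking_transform, locate_model,
                      pointer_to_tumor_distance, rib_frame,
                      random_rigid_transform)
from livernav.meshdist import MeshDistanceQuery, _closest_on_triangles


def _pose(position, rotation=None, t=0.0, tool="liver_sensor"):
    rot = rotation if rotation is not None else Rotation.identity()
    x, y, z = np.asarray(position, float)
    q = rot.as_quat()
    return PoseSample(t, tool, [x, y, z], [q[3], q[0], q[1], q[2]], 6)


def _chain(t1=None, t23=None, s_ref=None, tracker=None):
    t1 = t1 or RigidTransform(np.array([1.0, 0, 0, 0]), np.zeros(3), "mri", "cbct")
    t23 = t23 or RigidTransform(np.array([1.0, 0, 0, 0]), np.zeros(3), "cbct", "em")
    s_ref = s_ref or _pose([0.0, 0, 0])
    if tracker is None:
        rng = np.random.default_rng(0)
        tracker = rng.normal(scale=120.0, size=(6, 3))
    return build_chain(t1, t23, s_ref, tracker)


class TestLiverTracking:
    def test_same_pose_gives_identity(self):
        s = _pose([10.0, 20, 30], Rotation.from_euler("x", 30, degrees=True))
        assert liver_tracking_transform(s, s).is_identity(atol=1e-12)

    def test_pure_translation(self):
        ref = _pose([0.0, 0, 0])
        live = _pose([0.0, 0, 15.0], t=1.0)
        t = liver_tracking_transform(live, ref)
        assert np.allclose(t.translation, [0.0, 0, 15.0])
        assert t.rotation_angle_deg() < 1e-12

    def test_rotation_about_sensor_position(self):
        pos = np.array([50.0, -20.0, 10.0])
        rot = Rotation.from_euler("z", 30, degrees=True)
        ref = _pose(pos)
        live = _pose(pos, rot, t=1.0)
        t = liver_tracking_transform(live, ref)
        # closed form: rotation about the (stationary) sensor position
        point = pos + np.array([40.0, 0.0, 0.0])
        expected = pos + rot.apply(point - pos)
        assert np.allclose(t.apply(point), expected, atol=1e-9)
        # the sensor itself does not move
        assert np.allclose(t.apply(pos), pos, atol=1e-9)

    def test_five_dof_rejected(self):
        ref = _pose([0.0, 0, 0])
        five = PoseSample(1.0, "liver_sensor", [0, 0, 0], [0.0, 0, 1.0], 5)
        with pytest.raises(ValueError, match="6-DoF"):
            liver_tracking_transform(five, ref)

    def test_translation_only_mode_drops_lever_arm(self):
        pos = np.array([0.0, 0.0, 0.0])
        rot = Rotation.from_euler("y", 20, degrees=True)
        t_full = liver_tracking_transform(_pose(pos, rot, t=1.0), _pose(pos))
        t_trans = liver_tracking_transform(_pose(pos, rot, t=1.0), _pose(pos),
                                           translation_only=True)
        probe = np.array([100.0, 0.0, 0.0])
        assert np.linalg.norm(t_full.apply(probe) - probe) > 30.0
        assert np.allclose(t_trans.apply(probe), probe, atol=1e-12)


class TestChain:
    def test_valid_chain(self):
        chain = _chain()
        assert chain.model_frame == "mri"

    def test_gap_rejected(self):
        t1 = RigidTransform(np.array([1.0, 0, 0, 0]), np.zeros(3), "mri", "ct")
        t23 = RigidTransform(np.array([1.0, 0, 0, 0]), np.zeros(3), "cbct", "em")
        with pytest.raises(FrameError, match="T1"):
            build_chain(t1, t23, _pose([0.0, 0, 0]), np.zeros((6, 3)) + np.eye(6, 3))

    def test_five_dof_reference_rejected(self):
        five = PoseSample(0.0, "liver_sensor", [0, 0, 0], [0.0, 0, 1.0], 5)
        with pytest.raises(ValueError):
            _chain(s_ref=five)

    def test_locate_reduces_to_static_registration_at_snapshot(self, rng):
        t1 = random_rigid_transform(rng, "mri", "cbct", 30.0, 20.0)
        t23 = random_rigid_transform(rng, "cbct", "em", 30.0, 20.0)
        s_ref = _pose([12.0, 5.0, -3.0], Rotation.from_euler("x", 10, degrees=True))
        chain = _chain(t1, t23, s_ref)
        state = NavigationState(chain=chain, s_live=s_ref)
        pts = rng.normal(scale=60.0, size=(15, 3))
        assert np.allclose(locate_model(state, pts), (t23 @ t1).apply(pts), atol=1e-9)

    def test_rigid_scene_motion_tracked_exactly(self, scene, rng):
        # move liver + sensor by one rigid G: located target must follow exactly
        g = random_rigid_transform(rng, "em", "em", 25.0, 15.0)
        s_ref_pose = scene.liver_sensor_pose  # world == em here
        s_ref = _pose(s_ref_pose.translation, s_ref_pose.scipy_rotation)
        live_pose = g @ RigidTransform(s_ref_pose.rotation, s_ref_pose.translation,
                                       "liver_sensor_local", "em")
        s_live = _pose(live_pose.translation, live_pose.scipy_rotation, t=1.0)
        t1 = RigidTransform(np.array([1.0, 0, 0, 0]), np.zeros(3), "mri", "cbct")
        t23 = RigidTransform(np.array([1.0, 0, 0, 0]), np.zeros(3), "cbct", "em")
        chain = _chain(t1, t23, s_ref)
        state = NavigationState(chain=chain, s_live=s_live)
        located = locate_model(state, scene.tumor_centers)
        assert np.allclose(located, g.apply(scene.tumor_centers), atol=1e-9)


class TestRibFrame:
    def test_static_trackers_identity(self):
        chain = _chain()
        t, fre_val = rib_frame(chain.tracker_ref, chain)
        assert t.is_identity(atol=1e-9) and fre_val < 1e-9

    def test_whole_body_shift_cancels_in_relative_motion(self, rng):
        g = random_rigid_transform(rng, "em", "em", 30.0, 10.0)
        s_ref = _pose([20.0, 0.0, 40.0])
        chain = _chain(s_ref=s_ref)
        live_pose = g @ RigidTransform(s_ref.orientation, s_ref.position,
                                       "liver_sensor_local", "em")
        s_live = _pose(live_pose.translation, live_pose.scipy_rotation, t=1.0)
        state = NavigationState(chain=chain, s_live=s_live)
        rel = liver_relative_to_ribs(state, g.apply(chain.tracker_ref))
        assert rel.is_identity(atol=1e-9)

    def test_liver_only_motion_equals_tracking_transform(self):
        s_ref = _pose([0.0, 0, 0])
        chain = _chain(s_ref=s_ref)
        s_live = _pose([5.0, -2.0, 1.0], t=1.0)
        state = NavigationState(chain=chain, s_live=s_live)
        rel = liver_relative_to_ribs(state, chain.tracker_ref)  # ribs static
        assert np.allclose(rel.as_matrix(), state.tracking_transform.as_matrix(),
                           atol=1e-9)


class TestPointerDistance:
    def _state(self):
        return NavigationState(chain=_chain(), s_live=_pose([0.0, 0, 0]))

    def test_tip_on_vertex_is_zero(self):
        mesh = trimesh.creation.icosphere(2, radius=10.0)
        d, _ = pointer_to_tumor_distance(mesh.vertices[17], self._state(), mesh)
        assert d < 1e-9

    def test_sphere_closed_form(self):
        mesh = trimesh.creation.icosphere(4, radius=10.0)
        d, foot = pointer_to_tumor_distance([25.0, 0.0, 0.0], self._state(), mesh)
        assert d == pytest.approx(15.0, abs=0.02)  # icosphere chord error
        assert np.linalg.norm(foot - [10.0, 0, 0]) < 0.3

    def test_inside_tip_gives_zero(self):
        mesh = trimesh.creation.icosphere(3, radius=10.0)
        d, _ = pointer_to_tumor_distance([2.0, 1.0, 0.0], self._state(), mesh)
        assert d == 0.0

    def test_matches_all_triangles_oracle(self, scene, rng):
        mesh = scene.tumor_meshes[0]
        state = self._state()
        tris = np.asarray(mesh.triangles)
        for _ in range(50):
            tip = scene.tumor_centers[0] + rng.normal(scale=25.0, size=3)
            d, _ = pointer_to_tumor_distance(tip, state, mesh)
            brute = min(_closest_on_triangles(tip, tris)[0])
            inside = MeshDistanceQuery(mesh).contains(tip[None])[0]
            expected = 0.0 if inside else brute
            assert d == pytest.approx(expected, abs=1e-9)

    def test_empty_mesh_rejected(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            pointer_to_tumor_distance([0.0, 0, 0], self._state(), empty)


class TestStreamSmoothing:
    def test_constant_stream_unchanged(self):
        from livernav import smooth_stream
        samples = [_pose([5.0, 1.0, 2.0], t=0.1 * k) for k in range(10)]
        out = smooth_stream(samples, alpha=0.3)
        for s in out:
            assert np.allclose(s.position, [5.0, 1.0, 2.0], atol=1e-12)

    def test_jitter_variance_reduced(self, rng):
        from livernav import smooth_stream
        base = np.array([10.0, -5.0, 3.0])
        samples = [_pose(base + rng.normal(0, 1.0, 3), t=0.1 * k) for k in range(400)]
        out = smooth_stream(samples, alpha=0.2)
        raw_sd = np.array([s.position for s in samples]).std(axis=0).mean()
        smooth_sd = np.array([s.position for s in out[50:]]).std(axis=0).mean()
        assert smooth_sd < 0.6 * raw_sd

    def test_invalid_alpha(self):
        from livernav import smooth_stream
        with pytest.raises(ValueError):
            smooth_stream([], alpha=0.0)


class TestTargetZone:
    def test_point_at_sensor(self):
        state = NavigationState(chain=_chain(), s_live=_pose([10.0, 0, 0]))
        inside, d = in_target_zone([10.0, 0, 0], state)
        assert inside and d == 0.0

    def test_boundary_is_closed(self):
        state = NavigationState(chain=_chain(), s_live=_pose([0.0, 0, 0]))
        assert in_target_zone([50.0, 0, 0], state) == (True, 50.0)
        inside, d = in_target_zone([50.1, 0, 0], state)
        assert not inside and d == pytest.approx(50.1)

    def test_zone_radius_validated(self):
        with pytest.raises(ValueError):
            NavigationState(chain=_chain(), s_live=_pose([0.0, 0, 0]), zone_radius=0.0)
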