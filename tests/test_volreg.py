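"""Volume registration: bone masking, COM initialization, masked MI, ROI mode."""

import numpy as np
import pytest
from scipy import ndimage

from livernav import (ConfigError, EmptyMaskError, FrameError, RigidTransform,
                      VolumeImage, bone_mask, com_align, register_mi, register_roi,
                      RegistrationParams)
from livernav.rendering import LABEL_IDS, ct_fov, render_volume
from livernav.volreg import dilate_mask, evaluate_metric, roi_mask


def _identity(frame_from, frame_to):
    return RigidTransform(np.array([1.0, 0, 0, 0]), np.zeros(3), frame_from, frame_to)


def _textured_volume(seed, shape=(56, 56, 40), spacing=2.0, frame="fixed"):
    """Smooth random texture: enough structure for MI, cheap to build."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=shape)
    tex = ndimage.gaussian_filter(raw, 3.0) * 400.0 + 100.0
    return VolumeImage(tex.astype(np.float32), (spacing,) * 3, (0.0, 0.0, 0.0),
                       np.eye(3), frame)


class TestBoneMask:
    def test_count_matches_rendered_bone(self, scene):
        # fine enough voxels that the opening's one-voxel boundary erosion
        # stays a small fraction of the thin rib tubes
        vol, labels = render_volume(scene, (1.5,) * 3, ct_fov(), "ct", seed=0,
                                    with_labels=True)
        mask = bone_mask(vol, 600.0, 1600.0)
        true_count = int(np.sum(labels.voxels == LABEL_IDS["bone"]))
        assert mask.voxels.sum() == pytest.approx(true_count, rel=0.05)

    def test_all_air_volume_rejected(self):
        vol = VolumeImage(np.full((10, 10, 10), -1000.0), (1.0,) * 3, (0, 0, 0))
        with pytest.raises(EmptyMaskError):
            bone_mask(vol, 600.0, 1600.0)

    def test_degenerate_window_selects_everything(self, scene):
        vol = render_volume(scene, (4.0,) * 3, ct_fov(), "ct", seed=0)
        mask = bone_mask(vol, -2000.0, 4000.0)
        assert mask.voxels.all()

    def test_inverted_window_rejected(self, scene):
        vol = render_volume(scene, (4.0,) * 3, ct_fov(), "ct", seed=0)
        with pytest.raises(ConfigError):
            bone_mask(vol, 1600.0, 600.0)


class TestComAlign:
    def test_identical_masks_give_identity(self):
        m = VolumeImage(np.zeros((20, 20, 20), dtype=np.uint8), (1.0,) * 3, (0, 0, 0),
                        frame="a")
        m.voxels[5:10, 5:10, 5:10] = 1
        t = com_align(m, m)
        assert t.is_identity(atol=1e-12)

    def test_single_voxel_masks_exact_difference(self):
        a = VolumeImage(np.zeros((12, 12, 12), dtype=np.uint8), (2.0,) * 3, (0, 0, 0),
                        frame="fixed")
        b = VolumeImage(np.zeros((12, 12, 12), dtype=np.uint8), (2.0,) * 3, (0, 0, 0),
                        frame="moving")
        a.voxels[6, 7, 2] = 1
        b.voxels[1, 3, 8] = 1
        t = com_align(a, b)
        expected = a.index_to_world([6.0, 7, 2]) - b.index_to_world([1.0, 3, 8])
        assert np.allclose(t.translation, expected, atol=1e-12)
        assert (t.frame_from, t.frame_to) == ("moving", "fixed")

    def test_world_shifted_mask_recovered(self):
        m = VolumeImage(np.zeros((24, 24, 24), dtype=np.uint8), (2.0,) * 3, (0, 0, 0),
                        frame="moving")
        m.voxels[8:14, 6:16, 4:12] = 1
        shifted = VolumeImage(m.voxels.copy(), m.spacing, np.array([12.0, 0.0, -7.0]),
                              frame="fixed")
        t = com_align(shifted, m)
        assert np.allclose(t.translation, [12.0, 0.0, -7.0], atol=1e-9)

    def test_empty_mask_rejected(self):
        empty = VolumeImage(np.zeros((5, 5, 5), dtype=np.uint8), (1.0,) * 3, (0, 0, 0))
        with pytest.raises(EmptyMaskError):
            com_align(empty, empty)


class TestRegisterMi:
    def test_self_registration_stays_at_identity(self):
        vol = _textured_volume(0)
        res = register_mi(vol, VolumeImage(vol.voxels, vol.spacing, vol.origin,
                                           frame="moving"),
                          _identity("moving", "fixed"))
        assert res.transform.translation_norm() < 0.1
        assert res.transform.rotation_angle_deg() < 0.1

    def test_monotone_intensity_remap_invariance(self):
        vol = _textured_volume(1)
        remapped = np.sign(vol.voxels) * np.abs(vol.voxels) ** 1.5 / 10.0 + 200.0
        moving = VolumeImage(remapped.astype(np.float32), vol.spacing, vol.origin,
                             frame="moving")
        res = register_mi(vol, moving, _identity("moving", "fixed"))
        assert res.transform.translation_norm() < 2.0  # within 1 voxel
        assert res.transform.rotation_angle_deg() < 0.5

    def test_frame_mismatch_rejected(self):
        vol = _textured_volume(2)
        with pytest.raises(FrameError):
            register_mi(vol, vol, _identity("moving", "fixed"))

    def test_deterministic_bit_identical(self):
        fixed = _textured_volume(3)
        moving = VolumeImage(fixed.voxels.copy(), fixed.spacing,
                             fixed.origin + np.array([3.0, -2.0, 1.0]), frame="moving")
        a = register_mi(fixed, moving, _identity("moving", "fixed"))
        b = register_mi(fixed, moving, _identity("moving", "fixed"))
        assert np.array_equal(a.transform.rotation, b.transform.rotation)
        assert np.array_equal(a.transform.translation, b.transform.translation)
        assert a.metric == b.metric

    def test_metric_prefers_alignment_over_shifts(self):
        vol = _textured_volume(4)
        moving = VolumeImage(vol.voxels, vol.spacing, vol.origin, frame="moving")
        aligned = evaluate_metric(vol, moving, _identity("moving", "fixed"))
        for shift in ([4.0, 0, 0], [0, -4.0, 0], [0, 0, 6.0], [4.0, 4.0, 0]):
            t = RigidTransform(np.array([1.0, 0, 0, 0]), shift, "moving", "fixed")
            assert aligned < evaluate_metric(vol, moving, t)  # negative MI: lower = better

    def test_bad_params_rejected(self):
        with pytest.raises(ConfigError):
            RegistrationParams(bins=4)
        with pytest.raises(ConfigError):
            RegistrationParams(shrink_factors=(4, 2), smoothing_sigmas=(2.0,))


class TestRegisterRoi:
    def test_manual_mode_is_verbatim(self):
        vol = _textured_volume(5)
        moving = VolumeImage(vol.voxels, vol.spacing, vol.origin, frame="moving")
        manual = RigidTransform(np.array([1.0, 0, 0, 0]), [1.0, 2.0, 3.0],
                                "moving", "fixed")
        res = register_roi(vol, moving, (0, 0, 0), (10, 10, 10), manual=manual)
        assert res.transform is manual
        assert res.stop_condition == "manual pass-through"
        bad = RigidTransform(np.array([1.0, 0, 0, 0]), [1.0, 2.0, 3.0], "x", "fixed")
        with pytest.raises(FrameError):
            register_roi(vol, moving, (0, 0, 0), (10, 10, 10), manual=bad)

    def test_roi_outside_volume_rejected(self):
        vol = _textured_volume(6)
        with pytest.raises(ConfigError):
            roi_mask(vol, (1000.0, 1000, 1000), (1100.0, 1100, 1100))
        with pytest.raises(ConfigError):
            roi_mask(vol, (10.0, 10, 10), (0.0, 0, 0))

    def test_roi_registration_beats_whole_volume_under_remote_deformation(self):
        # moving = fixed with the ROI shifted by 5 mm but the (larger) remainder
        # shifted by -12 mm: only the ROI-restricted fit recovers the local offset
        fixed = _textured_volume(7, shape=(72, 48, 40))
        x_cut = 30  # index along x separating ROI side from the rest
        local, remote = np.array([5.0, 0, 0]), np.array([-12.0, 0, 0])
        vox = np.empty_like(fixed.voxels)
        # build moving by sampling fixed at x + shift (per region), via roll on
        # integer-voxel shifts (spacing 2 mm -> shifts of 2.5 / -6 voxels are
        # not integral; use interpolation)
        from scipy.ndimage import shift as nd_shift
        vox_local = nd_shift(fixed.voxels, -local / 2.0, order=1, mode="nearest")
        vox_remote = nd_shift(fixed.voxels, -remote / 2.0, order=1, mode="nearest")
        vox[:x_cut] = vox_local[:x_cut]
        vox[x_cut:] = vox_remote[x_cut:]
        moving = VolumeImage(vox, fixed.spacing, fixed.origin, frame="moving")
        roi_lo, roi_hi = (0.0, 0.0, 0.0), (2.0 * (x_cut - 8), 96.0, 80.0)
        res_roi = register_roi(fixed, moving, roi_lo, roi_hi,
                               init=_identity("moving", "fixed"))
        err_roi = np.linalg.norm(res_roi.transform.translation - local)
        res_all = register_mi(fixed, moving, _identity("moving", "fixed"))
        err_all = np.linalg.norm(res_all.transform.translation - local)
        assert err_roi < 2.0  # within 1 voxel
        assert err_all > 4.0  # whole-volume fit is pulled away (> 2 voxels)
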