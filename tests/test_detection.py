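"""Metal fiducial detection: sub-voxel centroids, tracker grouping, truncation QC."""

import numpy as np
import pytest

from livernav import (BlobDetection, CardinalityError, ConfigError, GroupingError,
                      FieldOfView, VolumeImage, detect_clips, detect_metal_blobs,
                      group_into_trackers, truncation_consistency, render_volume)
from livernav.phantom import Disc
from livernav.rendering import cbct_truncated_fov

VOXEL = 0.66  # the clinical CBCT reconstruction grid


def _disc_volume(center, normal=(0.0, 0.0, 1.0), extent=40.0, seed=0, noise=20.0):
    """Small local grid holding one rendered disc (Ø 8 x 2 mm) plus noise."""
    n = int(round(extent / VOXEL))
    vol = VolumeImage(np.full((n, n, n), 50.0, dtype=np.float32), (VOXEL,) * 3,
                      np.asarray(center, float) - (n - 1) * VOXEL / 2.0)
    disc = Disc(np.asarray(center, float), np.asarray(normal, float), 4.0, 2.0)
    sl = (slice(None),) * 3
    axes = [vol.origin[a] + VOXEL * np.arange(n) for a in range(3)]
    from livernav.rendering import _eval_on_subgrid
    occ = np.clip(0.5 - _eval_on_subgrid(disc.sdf, axes) / VOXEL, 0.0, 1.0)
    vol.voxels = (vol.voxels * (1 - occ) + 3000.0 * occ).astype(np.float32)
    if noise:
        vol.voxels += np.random.default_rng(seed).normal(0, noise, vol.shape).astype(np.float32)
    return vol


class TestDetectMetalBlobs:
    def test_no_metal_gives_empty_list(self):
        vol = VolumeImage(np.full((30, 30, 30), 100.0), (1.0,) * 3, (0, 0, 0))
        assert detect_metal_blobs(vol) == []

    def test_single_disc_centroid_subvoxel(self):
        center = np.array([10.0, -5.0, 3.0])
        blobs = detect_metal_blobs(_disc_volume(center), min_vol=20.0, max_vol=400.0)
        assert len(blobs) == 1
        assert np.linalg.norm(blobs[0].center - center) <= 0.33  # half a voxel

    def test_random_subvoxel_offsets(self):
        rng = np.random.default_rng(0)
        errors = []
        for k in range(20):
            center = rng.uniform(-VOXEL, VOXEL, 3)
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            blobs = detect_metal_blobs(_disc_volume(center, normal, seed=k),
                                       min_vol=20.0, max_vol=400.0)
            assert len(blobs) == 1
            errors.append(np.linalg.norm(blobs[0].center - center))
        errors = np.array(errors)
        assert errors.max() <= 0.5 * VOXEL
        assert errors.mean() <= 0.25 * VOXEL

    def test_merged_discs_filtered_by_size(self):
        # two discs face to face, touching: one connected component, double volume
        a = _disc_volume([0.0, 0.0, -0.9], noise=0.0)
        b = Disc(np.array([0.0, 0.0, 0.9]), np.array([0.0, 0, 1.0]), 4.0, 2.0)
        from livernav.rendering import _eval_on_subgrid
        axes = [a.origin[i] + VOXEL * np.arange(a.shape[i]) for i in range(3)]
        occ = np.clip(0.5 - _eval_on_subgrid(b.sdf, axes) / VOXEL, 0.0, 1.0)
        a.voxels = np.maximum(a.voxels, 50.0 * (1 - occ) + 3000.0 * occ).astype(np.float32)
        merged = detect_metal_blobs(a, min_vol=50.0, max_vol=150.0)
        assert merged == []  # ~200 mm^3 component exceeds max_vol
        loose = detect_metal_blobs(a, min_vol=50.0, max_vol=400.0)
        assert len(loose) == 1

    def test_intensity_scaling_invariance(self):
        center = np.array([0.0, 0.0, 0.0])
        vol = _disc_volume(center, noise=0.0)
        a = detect_metal_blobs(vol, min_vol=20.0, max_vol=400.0)
        scaled = vol.with_voxels(vol.voxels * 1.5)
        b = detect_metal_blobs(scaled, min_vol=20.0, max_vol=400.0)
        assert len(a) == len(b) == 1
        assert np.linalg.norm(a[0].center - b[0].center) < 0.2

    def test_principal_axes_sorted(self):
        blobs = detect_metal_blobs(_disc_volume([0.0, 0, 0]), min_vol=20.0, max_vol=400.0)
        axes = blobs[0].principal_axes_mm
        assert axes[0] >= axes[1] >= axes[2]


def _jittered_blobs(centers, rng, sigma=0.2):
    return [BlobDetection(c + rng.normal(0, sigma, 3), 100.0, 3000.0, (8.0, 8.0, 2.0))
            for c in centers]


class TestGrouping:
    def test_phantom_layout_recovered(self, scene, rng):
        blobs = _jittered_blobs(scene.tracker_discs.centers, rng)
        layout = group_into_trackers(blobs, 20.0)
        true = scene.tracker_discs
        for pair in layout.pairs:
            # both members of a recovered pair must match the same true pair
            owners = set()
            for p in pair:
                i = int(np.argmin(np.linalg.norm(true.centers - p, axis=1)))
                assert np.linalg.norm(true.centers[i] - p) < 1.0
                owners.add(i // 2)
            assert len(owners) == 1

    def test_clip_distractor_excluded(self, scene, rng):
        centers = scene.tracker_discs.centers
        distractor = centers[0] + np.array([47.0, 0.0, 0.0])
        blobs = _jittered_blobs(np.vstack([centers, distractor]), rng)
        layout = group_into_trackers(blobs, 20.0)
        dists = np.linalg.norm(layout.centers - distractor, axis=1)
        assert dists.min() > 10.0  # distractor not among the six

    def test_five_blobs_rejected(self, scene, rng):
        blobs = _jittered_blobs(scene.tracker_discs.centers[:5], rng)
        with pytest.raises(GroupingError):
            group_into_trackers(blobs, 20.0)

    def test_no_valid_pairing_reports_distances(self, rng):
        centers = rng.uniform(-100, 100, (6, 3))  # generic: no 20 mm pairs
        blobs = _jittered_blobs(centers, rng, sigma=0.0)
        with pytest.raises(GroupingError, match="candidate distances"):
            group_into_trackers(blobs, 20.0, tol=2.0)

    def test_random_scenes_with_distractors(self):
        hits = 0
        for k in range(30):
            rng = np.random.default_rng(1000 + k)
            from livernav import SceneConfig, generate_scene
            sc = generate_scene(SceneConfig(), seed=2000 + k)
            blobs = _jittered_blobs(
                np.vstack([sc.tracker_discs.centers, sc.clip_positions]), rng)
            try:
                layout = group_into_trackers(blobs, 20.0)
            except GroupingError:
                continue
            err = max(np.linalg.norm(layout.centers - c, axis=1).min()
                      for c in sc.tracker_discs.centers)
            hits += err < 2.0
        assert hits >= 29


class TestDetectClips:
    def test_clips_found_in_liver_roi(self, scene):
        lo = scene.clip_positions.min(axis=0) - 25.0
        hi = scene.clip_positions.max(axis=0) + 25.0
        vol = render_volume(scene, (VOXEL,) * 3, FieldOfView(
            tuple((lo + hi) / 2), tuple(hi - lo)), "cbct", seed=1)
        centers = detect_clips(vol, lo, hi)
        assert len(centers) == 4
        for c in centers:
            assert np.linalg.norm(scene.clip_positions - c, axis=1).min() <= 0.5

    def test_clip_outside_fov_omitted(self, scene):
        lo = scene.clip_positions.min(axis=0) - 25.0
        hi = scene.clip_positions.max(axis=0) + 25.0
        hi[0] = scene.clip_positions[:, 0].max() - 2.0  # crop one clip out
        vol = render_volume(scene, (VOXEL,) * 3, FieldOfView(
            tuple((lo + hi) / 2), tuple(hi - lo)), "cbct", seed=1)
        centers = detect_clips(vol, lo - 50.0, hi + 50.0)
        assert len(centers) < 4

    def test_empty_roi_rejected(self, scene):
        vol = VolumeImage(np.zeros((10, 10, 10)), (1.0,) * 3, (0, 0, 0))
        with pytest.raises(ConfigError):
            detect_clips(vol, (5.0, 5, 5), (1.0, 1, 1))


class TestTruncationConsistency:
    def test_identical_lists_zero(self, scene):
        disp, mean = truncation_consistency(scene.tracker_discs.centers,
                                            scene.tracker_discs.centers)
        assert np.all(disp == 0.0) and mean == 0.0

    def test_single_displacement_definition(self, scene):
        moved = scene.tracker_discs.centers.copy()
        moved[2] += np.array([VOXEL, 0.0, 0.0])
        disp, mean = truncation_consistency(scene.tracker_discs.centers, moved)
        assert mean == pytest.approx(VOXEL / 6)

    def test_cardinality_mismatch(self, scene):
        with pytest.raises(CardinalityError):
            truncation_consistency(scene.tracker_discs.centers,
                                   scene.tracker_discs.centers[:5])

    def test_full_vs_truncated_render_below_one_voxel(self, scene):
        spacing = (1.2,) * 3
        degraded = render_volume(scene, spacing, cbct_truncated_fov(), "cbct", seed=5)
        clean = render_volume(scene, spacing, FieldOfView(
            (0.0, 25.0, 0.0), (350.0, 350.0, 200.0)), "cbct", seed=5)
        layouts = []
        for vol in (clean, degraded):
            blobs = detect_metal_blobs(vol, min_vol=20.0, max_vol=400.0)
            layouts.append(group_into_trackers(blobs, 20.0))
        _, mean = truncation_consistency(layouts[0].centers, layouts[1].centers)
        assert mean < VOXEL
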