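"""End-to-end reproducible run: phantom -> detect -> register -> navigate -> evaluate.

``run_pipeline`` generates a ground-truth scene, renders the preoperative CT
and MRI and the intraoperative truncated-FOV CBCT, detects the metal
fiducials, builds the registration chain (T1 model->CBCT, T23 CBCT->EM, T4
CT->CBCT), captures the liver-sensor reference pose at the CBCT snapshot,
replays the noisy EM stream through the semi-rigid tracking model, and emits
guidance plus accuracy statistics in a JSON-serializable report.  Everything
is a pure function of the configuration and its seeds.

The phantom knows the truth at every step, so the report also carries the
errors a clinical system can never measure: transform errors against ground
truth and dense in-zone / out-of-zone TRE.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import rendering
from .accuracy import AccuracyRecord, accuracy_stats, image_distance, tre_profile
from .detection import detect_clips, detect_metal_blobs, group_into_trackers, truncation_consistency
from .errors import LiverNavError, StageError
from .fiducials import match_correspondence, register_points
from .geometry import PoseSample, RigidTransform, random_rigid_transform
from .navigation import (NavigationState, build_chain, in_target_zone,
                         liver_relative_to_ribs, locate_model)
from .phantom import (DeformationModel, EMNoiseModel, PhantomScene, SceneConfig,
                      default_manipulation_field, apply_deformation, generate_scene,
                      simulate_em_stream, TRACKER_TOOL_IDS)
from .volreg import (RegistrationParams, bone_mask, com_align, dilate_mask,
                     register_mi, register_roi)

log = logging.getLogger(__name__)


def _stage_clock():
    """Per-stage wall-time logger (informational only; timings never enter the
    report, which must stay byte-identical across runs)."""
    import time
    state = {"t": time.perf_counter()}

    def mark(stage: str) -> None:
        now = time.perf_counter()
        log.info("stage %-14s %.2f s", stage, now - state["t"])
        state["t"] = now

    return mark


@dataclass
class MotionConfig:
    """Scene trajectory around the CBCT snapshot (state = reference at snapshot)."""

    global_translation: tuple = (0.0, 0.0, 0.0)  # mm reached at end of stream
    global_rotation_deg: float = 0.0  # about a seed-drawn axis through the liver
    breathing_amplitude: tuple = (0.0, 0.0, 0.0)  # mm, cranio-caudal is z
    breathing_period: float = 4.0  # s
    manipulation_magnitude: float = 0.0  # mm, local field kernels
    manipulation_length_scale: float = 100.0  # mm
    rigid_core_radius: float = 30.0  # mm


@dataclass
class RunConfig:
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    em_sigma_pos: float = 0.5  # mm
    em_sigma_rot: float = 0.3  # degrees
    zone_radius: float = 50.0  # mm
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    spacing_ct: tuple = (2.5, 2.5, 2.5)  # mm
    spacing_cbct: tuple = (1.2, 1.2, 1.2)  # mm
    spacing_mri: tuple = (2.5, 2.5, 2.5)  # mm
    stream_rate: float = 10.0  # Hz
    stream_duration: float = 3.0  # s
    cbct_snapshot_time: float = 0.0  # s
    frame_offset_translation: float = 30.0  # mm, inter-frame ground-truth offsets
    frame_offset_angle_deg: float = 8.0
    t1_mode: str = "manual"  # "manual" reproduces the clinical step; "auto" = ROI MI
    exact_fiducials: bool = False  # bypass image detection with ground-truth centers
    run_t4: bool = True
    truncation_check: bool = True
    n_observers: int = 3
    observer_sigma: float = 1.0  # mm jitter per simulated observer
    n_tre_sample_points: int = 60

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _make_trajectory(
    scene_ref: PhantomScene, config: RunConfig, rng: np.random.Generator
) -> tuple[Callable[[float], PhantomScene], DeformationModel]:
    """Scene state as a function of time; identical to the reference at the snapshot."""
    m = config.motion
    t0 = config.cbct_snapshot_time
    span = max(config.stream_duration, 1e-6)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    pivot = np.asarray(scene_ref.primitives["liver"].center, float)
    t_end = np.asarray(m.global_translation, float)
    ang_end = np.radians(m.global_rotation_deg)

    def global_traj(t: float) -> RigidTransform:
        a = (t - t0) / span
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec(axis * (ang_end * a))
        # rotate about the liver center, then translate
        trans = t_end * a + pivot - rot.apply(pivot)
        return RigidTransform.from_rotation(rot, trans, scene_ref.frame, scene_ref.frame)

    local = None
    if m.manipulation_magnitude > 0:
        local = default_manipulation_field(
            scene_ref, magnitude=m.manipulation_magnitude,
            length_scale=m.manipulation_length_scale,
            core_radius=m.rigid_core_radius, seed=_sub_seed(rng))
    model = DeformationModel(
        global_trajectory=global_traj,
        breathing_amplitude=np.asarray(m.breathing_amplitude, float),
        breathing_period=m.breathing_period,
        local_field=local,
        field_envelope=lambda t: (t - t0) / span,
    )

    def trajectory(t: float) -> PhantomScene:
        return apply_deformation(scene_ref, model, t)

    return trajectory, model


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the JSON-serializable run report."""
    report: dict = {"config": config.to_dict(), "stages": {}}
    mark_stage = _stage_clock()
    rng = np.random.default_rng(config.seed)
    seed_scene = _sub_seed(rng)
    seed_frames = _sub_seed(rng)
    seed_render_ct = _sub_seed(rng)
    seed_render_cbct = _sub_seed(rng)
    seed_render_mri = _sub_seed(rng)
    seed_em = _sub_seed(rng)
    seed_traj = _sub_seed(rng)
    seed_obs = _sub_seed(rng)
    seed_tre = _sub_seed(rng)

    # ---- stage: phantom ----------------------------------------------------
    try:
        scene = generate_scene(config.scene, seed_scene, frame="world")
        frame_rng = np.random.default_rng(seed_frames)
        offsets = {}
        for name in ("mri", "ct", "cbct", "em"):
            offsets[name] = random_rigid_transform(
                frame_rng, "world", name,
                max_translation=config.frame_offset_translation,
                max_angle_deg=config.frame_offset_angle_deg)
        t1_true = offsets["cbct"] @ offsets["mri"].invert()
        t23_true = offsets["em"] @ offsets["cbct"].invert()
        t4_true = offsets["cbct"] @ offsets["ct"].invert()
        scene_cbct = scene.transformed(offsets["cbct"])
        report["stages"]["phantom"] = {"n_tumors": len(scene.tumor_meshes)}
    except LiverNavError as exc:
        raise StageError("phantom", str(exc)) from exc
    mark_stage("phantom")

    # ---- stage: render -----------------------------------------------------
    use_rendering = (not config.exact_fiducials) or config.run_t4 or config.truncation_check
    vol_cbct = labels_cbct = None
    if use_rendering:
        try:
            cbct_center = tuple(offsets["cbct"].apply(np.array([0.0, 25.0, 0.0])))
            vol_cbct, labels_cbct = rendering.render_volume(
                scene_cbct, config.spacing_cbct,
                rendering.cbct_truncated_fov(cbct_center), "cbct",
                seed=seed_render_cbct, with_labels=True)
            report["stages"]["render"] = {"cbct_shape": list(vol_cbct.shape)}
        except LiverNavError as exc:
            raise StageError("render", str(exc)) from exc
        mark_stage("render")

    # ---- stage: detect -----------------------------------------------------
    try:
        if config.exact_fiducials:
            disc_centers_cbct = scene_cbct.tracker_discs.centers
            clip_centers_cbct = scene_cbct.clip_positions
        else:
            blobs = detect_metal_blobs(vol_cbct, min_vol=20.0, max_vol=400.0)
            layout = group_into_trackers(
                blobs, config.scene.disc_pairing_distance, tol=2.0)
            disc_centers_cbct = layout.centers
            liver_bounds = scene_cbct.primitives["liver"].bounds()
            clip_centers_cbct = detect_clips(
                vol_cbct, liver_bounds[0] - 10.0, liver_bounds[1] + 10.0)
            # the loose axis-aligned liver box can graze a tracker disc; a disc
            # sliced by the ROI edge mimics a clip-sized blob. The discs are
            # known objects by now - drop clip candidates near them.
            if len(clip_centers_cbct):
                d_disc = np.linalg.norm(
                    clip_centers_cbct[:, None, :] - disc_centers_cbct[None], axis=2
                ).min(axis=1)
                clip_centers_cbct = clip_centers_cbct[d_disc > 15.0]
            if len(clip_centers_cbct) != config.scene.n_clips:
                raise StageError(
                    "detect",
                    f"found {len(clip_centers_cbct)} clips, expected {config.scene.n_clips}")
        report["stages"]["detect"] = {
            "n_discs": int(len(disc_centers_cbct)),
            "n_clips": int(len(clip_centers_cbct)),
        }
    except LiverNavError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError("detect", str(exc)) from exc
    mark_stage("detect")

    # ---- stage: truncation QC ---------------------------------------------
    if config.truncation_check and not config.exact_fiducials:
        try:
            vol_full = rendering.render_volume(
                scene_cbct, config.spacing_cbct,
                rendering.FieldOfView(cbct_center, (350.0, 350.0, 200.0)),
                "cbct", seed=seed_render_cbct)
            blobs_full = detect_metal_blobs(vol_full, min_vol=20.0, max_vol=400.0)
            layout_full = group_into_trackers(
                blobs_full, config.scene.disc_pairing_distance, tol=2.0)
            _, mean_disp = truncation_consistency(layout_full.centers, disc_centers_cbct)
            report["stages"]["truncation_qc"] = {"mean_displacement_mm": mean_disp}
        except LiverNavError as exc:
            raise StageError("truncation_qc", str(exc)) from exc
        mark_stage("truncation_qc")

    # ---- stage: em stream --------------------------------------------------
    try:
        traj_rng = np.random.default_rng(seed_traj)
        trajectory, motion_model = _make_trajectory(scene, config, traj_rng)
        noise = EMNoiseModel(config.em_sigma_pos, config.em_sigma_rot, seed_em)
        stream = simulate_em_stream(
            trajectory, noise, rate=config.stream_rate,
            duration=config.stream_duration, world_to_em=offsets["em"])
        report["stages"]["em_stream"] = {"n_samples": len(stream)}
    except LiverNavError as exc:
        raise StageError("em_stream", str(exc)) from exc
    mark_stage("em_stream")

    # ---- stage: register ---------------------------------------------------
    try:
        # snapshot: samples nearest the declared CBCT acquisition time
        liver_samples = [s for s in stream if s.tool_id == "liver_sensor"]
        times = np.array([s.timestamp for s in liver_samples])
        i_ref = int(np.argmin(np.abs(times - config.cbct_snapshot_time)))
        s_ref = liver_samples[i_ref]
        t_ref = s_ref.timestamp
        tracker_ref = np.array([
            next(s.position for s in stream
                 if s.tool_id == tool and s.timestamp == t_ref)
            for tool in TRACKER_TOOL_IDS])

        fids_t23 = match_correspondence(
            disc_centers_cbct, tracker_ref, frame_src="cbct", frame_dst="em")
        t23_est, fre_t23 = register_points(fids_t23)
        report["stages"]["register"] = {
            "fre_t23_mm": fre_t23,
            "t23_translation_error_mm": float(np.linalg.norm(
                t23_est.translation - t23_true.translation)),
            "t23_rotation_error_deg": (t23_est.invert() @ t23_true).rotation_angle_deg(),
        }

        if config.run_t4:
            scene_ct = scene.transformed(offsets["ct"])
            ct_center = tuple(offsets["ct"].apply(np.array([0.0, 5.0, 0.0])))
            vol_ct = rendering.render_volume(
                scene_ct, config.spacing_ct, rendering.ct_fov(ct_center), "ct",
                seed=seed_render_ct, include=rendering.PREOP_GROUPS)
            mask_ct = bone_mask(vol_ct, config.registration.bone_lo,
                                config.registration.bone_hi)
            mask_cbct = bone_mask(vol_cbct, config.registration.bone_lo,
                                  config.registration.bone_hi)
            init_t4 = com_align(mask_cbct, mask_ct)
            dil = config.registration.mask_dilation
            mi = register_mi(vol_cbct, vol_ct, init_t4,
                             fixed_mask=dilate_mask(mask_cbct, dil),
                             moving_mask=dilate_mask(mask_ct, dil),
                             params=config.registration)
            t4_est = mi.transform
            err_t = float(np.linalg.norm(t4_est.translation - t4_true.translation))
            err_r = (t4_est.invert() @ t4_true).rotation_angle_deg()
            report["stages"]["register"].update({
                "t4_metric": mi.metric,
                "t4_converged": mi.converged,
                "t4_translation_error_mm": err_t,
                "t4_rotation_error_deg": err_r,
            })
        else:
            t4_est = None

        if config.t1_mode == "manual":
            t1_est = t1_true  # the clinical step was interactive; pass the truth through
        else:
            scene_mri = scene.transformed(offsets["mri"])
            mri_center = tuple(offsets["mri"].apply(np.zeros(3)))
            vol_mri = rendering.render_volume(
                scene_mri, config.spacing_mri, rendering.mri_fov(mri_center), "mri",
                seed=seed_render_mri, include=rendering.PREOP_GROUPS)
            tumor_cbct = scene_cbct.tumor_centers[0]
            init_t1 = com_align(_body_mask(vol_cbct, -500.0), _body_mask(vol_mri, 100.0))
            roi = register_roi(vol_cbct, vol_mri, tumor_cbct - 60.0, tumor_cbct + 60.0,
                               init=init_t1, params=config.registration)
            t1_est = roi.transform
            report["stages"]["register"].update({
                "t1_translation_error_mm": float(np.linalg.norm(
                    t1_est.translation - t1_true.translation)),
                "t1_rotation_error_deg": (t1_est.invert() @ t1_true).rotation_angle_deg(),
            })
        chain = build_chain(t1_est, t23_est, s_ref, tracker_ref, t4_est)
    except LiverNavError as exc:
        raise StageError("register", str(exc)) from exc
    mark_stage("register")

    # ---- stage: navigate (replay) ------------------------------------------
    try:
        tre_rng = np.random.default_rng(seed_tre)
        pts_world = np.vstack([
            scene.tumor_centers,
            scene.clip_positions,
            scene.liver_sample_points(config.n_tre_sample_points, _sub_seed(tre_rng)),
        ])
        pts_mri = offsets["mri"].apply(pts_world)
        by_time: dict[float, dict[str, PoseSample]] = {}
        for s in stream:
            by_time.setdefault(s.timestamp, {})[s.tool_id] = s

        rows = []
        states, truths = [], []
        for t in sorted(by_time):
            tools = by_time[t]
            state = NavigationState(chain=chain, s_live=tools["liver_sensor"],
                                    zone_radius=config.zone_radius)
            scene_t = trajectory(t)
            true_em = offsets["em"].apply(scene_t.reference_map.forward(pts_world))
            located = locate_model(state, pts_mri)
            tre = np.linalg.norm(located - true_em, axis=1)
            in_zone = np.array([in_target_zone(p, state)[0] for p in located])
            tracker_live = np.array([tools[tool].position for tool in TRACKER_TOOL_IDS])
            rel = liver_relative_to_ribs(state, tracker_live)
            tumor_in_zone, tumor_sensor_dist = in_target_zone(located[0], state)
            rows.append({
                "timestamp": t,
                "tumor_x_mm": located[0][0], "tumor_y_mm": located[0][1],
                "tumor_z_mm": located[0][2],
                "tumor_in_zone": bool(tumor_in_zone),
                "tumor_sensor_distance_mm": tumor_sensor_dist,
                "liver_vs_ribs_translation_mm": rel.translation_norm(),
                "liver_vs_ribs_rotation_deg": rel.rotation_angle_deg(),
                "mean_tre_mm": float(tre.mean()),
                "max_tre_mm": float(tre.max()),
                "mean_tre_in_zone_mm": float(tre[in_zone].mean()) if in_zone.any() else float("nan"),
                "max_tre_in_zone_mm": float(tre[in_zone].max()) if in_zone.any() else float("nan"),
            })
            states.append(state)
            truths.append(true_em)
        guidance = pd.DataFrame(rows)
        profile = tre_profile(states, pts_mri, truths)
        in_zone_max = float(np.nanmax(guidance["max_tre_in_zone_mm"].to_numpy()))
        report["stages"]["navigate"] = {
            "n_frames": len(rows),
            "max_tre_in_zone_mm": in_zone_max,
            "mean_tre_in_zone_mm": float(np.nanmean(guidance["mean_tre_in_zone_mm"].to_numpy())),
            "tre_profile": profile.to_dict(orient="records"),
        }
    except LiverNavError as exc:
        raise StageError("navigate", str(exc)) from exc
    mark_stage("navigate")

    # ---- stage: evaluate ---------------------------------------------------
    try:
        obs_rng = np.random.default_rng(seed_obs)
        t_last = sorted(by_time)[-1]
        state = states[-1]
        scene_t = trajectory(t_last)
        records = []
        tumor_mesh_mri = scene.tumor_meshes[0].copy()
        tumor_mesh_mri.apply_transform(offsets["mri"].as_matrix())
        from .navigation import pointer_to_tumor_distance
        for i, clip_world in enumerate(scene.clip_positions):
            clip_live_em = offsets["em"].apply(
                scene_t.reference_map.forward(clip_world[None]))[0]
            d_nav, _ = pointer_to_tumor_distance(clip_live_em, state, tumor_mesh_mri)
            clip_cbct = clip_centers_cbct[
                int(np.argmin(np.linalg.norm(
                    clip_centers_cbct - scene_cbct.clip_positions[i], axis=1)))]
            d_true = image_distance(clip_cbct, scene_cbct.tumor_meshes[0])
            observers = tuple(
                max(0.0, d_true + obs_rng.normal(0.0, config.observer_sigma))
                for _ in range(config.n_observers))
            records.append(AccuracyRecord(f"clip_{i}", d_nav, observer_values=observers))
        stats = accuracy_stats(records)
        report["stages"]["evaluate"] = {
            "records": [
                {"marker_id": r.marker_id, "d_nav_mm": r.d_nav, "d_img_mm": r.d_img}
                for r in records
            ],
            **{k: v for k, v in stats.items()},
        }
    except LiverNavError as exc:
        raise StageError("evaluate", str(exc)) from exc
    mark_stage("evaluate")

    report["guidance"] = guidance.to_dict(orient="records")
    return report


def _body_mask(vol, threshold: float):
    """Everything above the air/background level — a crude whole-body mask."""
    mask = (vol.voxels > threshold).astype(np.uint8)
    if not mask.any():
        raise StageError("register", "body mask is empty")
    return vol.with_voxels(mask)
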