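"""Readers and writers for every on-disk format the pipeline touches.

Volumes go through SimpleITK (NIfTI ``.nii``/``.nii.gz`` and MetaImage
``.mha``/``.mhd``), preserving voxels bit-exactly and grid metadata.
Transforms are a plain-text 4x4 homogeneous matrix plus a JSON sidecar
carrying the frame labels.  Pose streams are JSON-lines (one sample per
line), append-friendly and replayable; per-tool timestamp monotonicity is
validated on read.  Fiducials are CSV; meshes STL (binary) with PLY accepted
on input; run configuration YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
import trimesh
import yaml

from .errors import FormatError
from .geometry import PoseSample, RigidTransform, validate_stream
from .volume import VolumeImage

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(
            f"unsupported volume format '{path.name}' (supported: {_VOLUME_SUFFIXES})")


def read_volume(path, frame: str = "world") -> VolumeImage:
    path = Path(path)
    _check_volume_path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # ITK wraps header errors in RuntimeError
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    return VolumeImage.from_sitk(img, frame=frame)


def write_volume(vol: VolumeImage, path) -> None:
    path = Path(path)
    _check_volume_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(vol.to_sitk(), str(path))


def write_transform(t: RigidTransform, path) -> None:
    """4x4 row-major text matrix + '<path>.json' sidecar with the frame labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, t.as_matrix(), fmt="%.17g")
    sidecar = {"frame_from": t.frame_from, "frame_to": t.frame_to}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True) + "\n")


def read_transform(path, frame_from: str = None, frame_to: str = None) -> RigidTransform:
    """Read a transform; frame labels come from the sidecar unless given explicitly."""
    path = Path(path)
    try:
        m = np.loadtxt(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read transform matrix {path}: {exc}") from exc
    sidecar = Path(str(path) + ".json")
    if frame_from is None or frame_to is None:
        if not sidecar.exists():
            raise FormatError(
                f"no frame labels: sidecar {sidecar} missing and none supplied")
        meta = json.loads(sidecar.read_text())
        frame_from = frame_from or meta.get("frame_from")
        frame_to = frame_to or meta.get("frame_to")
    try:
        return RigidTransform.from_matrix(m, frame_from, frame_to)
    except ValueError as exc:
        raise FormatError(f"invalid transform in {path}: {exc}") from exc


def write_pose_stream(samples: Sequence[PoseSample], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in samples:
            fh.write(json.dumps({
                "timestamp": s.timestamp,
                "tool_id": s.tool_id,
                "dof": s.dof,
                "position": [float(v) for v in s.position],
                "orientation": [float(v) for v in s.orientation],
            }, sort_keys=True) + "\n")


def read_pose_stream(path) -> list[PoseSample]:
    path = Path(path)
    samples: list[PoseSample] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                samples.append(PoseSample(
                    timestamp=float(rec["timestamp"]),
                    tool_id=str(rec["tool_id"]),
                    position=rec["position"],
                    orientation=rec["orientation"],
                    dof=int(rec["dof"]),
                ))
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                raise FormatError(f"{path}:{lineno}: invalid pose sample: {exc}") from exc
    try:
        validate_stream(samples)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return samples


def write_chain(chain, path) -> None:
    """Registration chain as JSON: matrices with frame labels, the reference
    liver pose and the six tracker reference positions."""
    from .navigation import RegistrationChain  # local import: io has no nav deps

    assert isinstance(chain, RegistrationChain)
    data = {
        "t1": {"matrix": chain.t1.as_matrix().tolist(),
               "frame_from": chain.t1.frame_from, "frame_to": chain.t1.frame_to},
        "t23": {"matrix": chain.t23.as_matrix().tolist(),
                "frame_from": chain.t23.frame_from, "frame_to": chain.t23.frame_to},
        "s_ref": {"timestamp": chain.s_ref.timestamp, "tool_id": chain.s_ref.tool_id,
                  "position": chain.s_ref.position.tolist(),
                  "orientation": chain.s_ref.orientation.tolist(), "dof": 6},
        "tracker_ref": chain.tracker_ref.tolist(),
    }
    if chain.t4 is not None:
        data["t4"] = {"matrix": chain.t4.as_matrix().tolist(),
                      "frame_from": chain.t4.frame_from, "frame_to": chain.t4.frame_to}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data, sort_keys=True, indent=2) + "\n")


def read_chain(path):
    from .navigation import build_chain

    try:
        data = json.loads(Path(path).read_text())

        def transform(key):
            entry = data[key]
            return RigidTransform.from_matrix(np.asarray(entry["matrix"]),
                                              entry["frame_from"], entry["frame_to"])

        s = data["s_ref"]
        s_ref = PoseSample(float(s["timestamp"]), str(s["tool_id"]), s["position"],
                           s["orientation"], int(s["dof"]))
        t4 = transform("t4") if "t4" in data else None
        return build_chain(transform("t1"), transform("t23"), s_ref,
                           np.asarray(data["tracker_ref"], float), t4=t4)
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"invalid chain file {path}: {exc}") from exc


def write_fiducials_csv(labels, positions, frame: str, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    positions = np.asarray(positions, float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("label,x,y,z,frame\n")
        for lab, p in zip(labels, positions):
            fh.write(f"{lab},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g},{frame}\n")


def read_fiducials_csv(path) -> tuple[list, np.ndarray, str]:
    path = Path(path)
    labels, rows, frames = [], [], set()
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:4] != ["label", "x", "y", "z"]:
            raise FormatError(f"{path}: expected header label,x,y,z[,frame]")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                labels.append(parts[0])
                rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad fiducial row: {exc}") from exc
            if len(parts) > 4:
                frames.add(parts[4])
    if len(frames) > 1:
        raise FormatError(f"{path}: mixed frames {sorted(frames)}")
    frame = frames.pop() if frames else "unknown"
    return labels, np.asarray(rows, float).reshape(-1, 3), frame


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))


def read_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise FormatError(f"unsupported mesh format '{path.suffix}' (STL or PLY)")
    try:
        out = trimesh.load(str(path), force="mesh")
    except Exception as exc:
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    return out


def write_yaml(data: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(data, sort_keys=True))


def read_yaml(path) -> dict:
    try:
        return yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"invalid YAML in {path}: {exc}") from exc


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json_report(data: dict, path) -> None:
    """Deterministic JSON (sorted keys, fixed float repr) so identical runs
    produce byte-identical reports."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(data, sort_keys=True, indent=2, default=_json_default) + "\n")
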