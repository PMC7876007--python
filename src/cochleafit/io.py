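"""Readers and writers for every artifact the pipeline touches.

All I/O is in mm; nothing rescales silently.  Conventions (enforced, stated
once): zero-based voxel indices, voxel-center world mapping
``world = origin + index * spacing``, axial slices along the third axis.
Volumes must be isotropic to enter the pipeline; anisotropic files are
rejected with an explicit message rather than resampled behind the caller's
back.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .errors import FormatError, SchemaError
from .registration import LANDMARK_NAMES
from .ssm import StatisticalShapeModel
from .volume import Volume

_VOLUME_EXT = (".nii", ".nii.gz", ".mha", ".mhd")
_MESH_EXT = (".ply", ".stl", ".obj")


def _check_ext(path: Path, allowed, kind: str) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in allowed):
        raise FormatError(f"unsupported {kind} format for {path}; "
                          f"expected one of {allowed}")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume(vol: Volume, path) -> None:
    path = Path(path)
    _check_ext(path, _VOLUME_EXT, "volume")
    # our array is (x, y, z); ITK stores (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(np.asarray(vol.data, np.float64), (2, 1, 0))))
    img.SetSpacing((float(vol.spacing),) * 3)
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> Volume:
    path = Path(path)
    _check_ext(path, _VOLUME_EXT, "volume")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    spacing = np.asarray(img.GetSpacing(), float)
    if not np.allclose(spacing, spacing[0], rtol=1e-6, atol=1e-9):
        raise FormatError(
            f"{path}: anisotropic spacing {tuple(spacing)} mm is not "
            "supported; resample to isotropic voxels first")
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume(data, float(spacing[0]), np.asarray(img.GetOrigin(), float))


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    _check_ext(path, _MESH_EXT, "mesh")
    mesh.export(str(path))


def read_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    _check_ext(path, _MESH_EXT, "mesh")
    try:
        mesh = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # trimesh raises various types
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    return mesh


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def write_landmarks(landmarks: dict, path) -> None:
    missing = [n for n in LANDMARK_NAMES if n not in landmarks]
    if missing:
        raise SchemaError(f"landmark set is missing {missing}")
    payload = {n: [float(x) for x in np.asarray(landmarks[n], float)]
               for n in LANDMARK_NAMES}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_landmarks(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    missing = [n for n in LANDMARK_NAMES if n not in raw]
    if missing:
        raise SchemaError(f"{path}: landmark file is missing {missing}")
    return {n: np.asarray(raw[n], float) for n in LANDMARK_NAMES}


# ---------------------------------------------------------------------------
# shape models
# ---------------------------------------------------------------------------

def write_model(model: StatisticalShapeModel, path) -> None:
    """Store a fitted shape model as <path>.npz plus a JSON sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    np.savez(base.with_suffix(".npz"),
             mean=model.mean_, components=model.components_,
             eigenvalues=model.eigenvalues_)
    sidecar = {
        "n_training": int(model.n_training_),
        "n_vertices": int(model.n_vertices_),
        "n_modes": int(len(model.components_)),
        "eigenvalues": [float(e) for e in model.eigenvalues_],
    }
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_model(path) -> StatisticalShapeModel:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    npz = base.with_suffix(".npz")
    side = base.with_suffix(".json")
    if not npz.exists() or not side.exists():
        raise FormatError(f"model container incomplete: need {npz} and {side}")
    arrays = np.load(npz)
    with open(side) as fh:
        meta = json.load(fh)
    model = StatisticalShapeModel()
    model.mean_ = arrays["mean"]
    model.components_ = arrays["components"]
    model.eigenvalues_ = arrays["eigenvalues"]
    model.n_training_ = int(meta["n_training"])
    model.n_vertices_ = int(meta["n_vertices"])
    return model


# ---------------------------------------------------------------------------
# point clouds and reports
# ---------------------------------------------------------------------------

def write_cloud(points: np.ndarray, path) -> None:
    """XYZ text or PLY point export."""
    path = Path(path)
    pts = np.asarray(points, float)
    if path.suffix.lower() == ".xyz":
        np.savetxt(path, pts, fmt="%.9g")
    elif path.suffix.lower() == ".ply":
        trimesh.PointCloud(pts).export(str(path))
    else:
        raise FormatError(f"unsupported cloud format {path.suffix}")


def read_cloud(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return np.atleast_2d(np.loadtxt(path))
    if path.suffix.lower() == ".ply":
        return np.asarray(trimesh.load(str(path)).vertices, float)
    raise FormatError(f"unsupported cloud format {path.suffix}")


def write_report(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
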