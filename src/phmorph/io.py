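"""File formats: STL/PLY meshes, landmark/ground-truth JSON, CSV tables.

Meshes are read and written through :mod:`trimesh` with vertex processing
disabled so coordinates pass through untouched; units are asserted to be
millimetres, never inferred or rescaled.  STL stores float32 coordinates, so
vertices are cast to float32 on STL export and duplicated per-facet vertices
are merged deterministically on import (first-occurrence order); ASCII and
binary STL of the same mesh therefore decode to the identical TriMesh.

Landmarks travel as a small JSON schema with keys ``junction``,
``anteroinferior`` and ``posteroinferior`` (each ``[x, y, z]`` in mm).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .pipeline import LandmarkSet, MorphometryResult, TriMesh

__all__ = [
    "MeshFormatError",
    "LandmarkSchemaError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "snap_landmarks",
    "read_cohort",
    "write_cohort",
    "write_result",
    "write_ground_truth",
]

logger = logging.getLogger("phmorph.io")

_LANDMARK_KEYS = ("junction", "anteroinferior", "posteroinferior")


class MeshFormatError(ValueError):
    """Unreadable, empty or face-less mesh file."""


class LandmarkSchemaError(ValueError):
    """Landmark JSON missing keys or holding non-finite coordinates."""


def _merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray):
    """Merge exactly-equal vertices, keeping first-occurrence order."""
    _, first, inverse = np.unique(vertices, axis=0, return_index=True,
                                  return_inverse=True)
    order = np.argsort(first)               # first-occurrence order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[first[order]], rank[inverse][faces]


def read_mesh(path, units: str = "mm") -> TriMesh:
    """Load an STL or PLY surface; coordinates are taken as millimetres."""
    if units != "mm":
        raise ValueError("only millimetre meshes are supported; convert first")
    path = Path(path)
    if not path.is_file():
        raise MeshFormatError(f"{path}: no such file")
    try:
        loaded = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise MeshFormatError(f"{path}: unreadable mesh ({exc})") from exc
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise MeshFormatError(f"{path}: mesh has no faces")
    if path.suffix.lower() == ".stl":
        vertices, faces = _merge_duplicate_vertices(vertices, faces)
    try:
        return TriMesh(vertices, faces)
    except ValueError as exc:
        raise MeshFormatError(f"{path}: invalid mesh ({exc})") from exc


def write_mesh(mesh: TriMesh, path, ascii_stl: bool = False) -> None:
    """Write STL (binary by default, ASCII on request) or PLY."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        # Cast to the STL storage type up front so the ASCII and binary
        # dialects of one mesh are bit-for-bit equivalent after reading.
        tm = trimesh.Trimesh(vertices=mesh.vertices.astype(np.float32),
                             faces=mesh.faces, process=False)
        data = trimesh.exchange.stl.export_stl_ascii(tm) if ascii_stl \
            else trimesh.exchange.stl.export_stl(tm)
        mode = "w" if isinstance(data, str) else "wb"
        with open(path, mode) as fh:
            fh.write(data)
    elif suffix == ".ply":
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                             process=False)
        tm.export(str(path))
    else:
        raise MeshFormatError(f"{path}: unsupported mesh format {suffix!r}")


def read_landmarks(path, mesh: TriMesh | None = None,
                   snap: bool = False, snap_mm: float = 2.0) -> LandmarkSet:
    """Read the landmark JSON; optionally snap each point to the mesh."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise LandmarkSchemaError(f"{path}: unreadable landmark file ({exc})") \
            from exc
    pts = []
    for key in _LANDMARK_KEYS:
        if key not in payload:
            raise LandmarkSchemaError(f"{path}: missing landmark key {key!r}")
        p = np.asarray(payload[key], dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise LandmarkSchemaError(
                f"{path}: landmark {key!r} is not a finite [x, y, z] triple")
        pts.append(p)
    try:
        landmarks = LandmarkSet(*pts)
    except ValueError as exc:
        raise LandmarkSchemaError(f"{path}: {exc}") from exc
    if snap:
        if mesh is None:
            raise ValueError("snapping landmarks requires the mesh")
        landmarks = snap_landmarks(landmarks, mesh, snap_mm)
    return landmarks


def snap_landmarks(landmarks: LandmarkSet, mesh: TriMesh,
                   snap_mm: float = 2.0) -> LandmarkSet:
    """Replace each landmark by its nearest mesh vertex; log large moves."""
    tree = cKDTree(mesh.vertices)
    dist, idx = tree.query(landmarks.as_array())
    for key, d in zip(_LANDMARK_KEYS, dist):
        if d > snap_mm:
            logger.warning("landmark %s was %.2f mm off-surface (snap limit "
                           "%.2f mm); snapped to nearest vertex", key, d, snap_mm)
    return LandmarkSet(*mesh.vertices[idx])


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    payload = {
        "junction": [float(v) for v in landmarks.p_junction],
        "anteroinferior": [float(v) for v in landmarks.p_anteroinferior],
        "posteroinferior": [float(v) for v in landmarks.p_posteroinferior],
        "units": "mm",
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_cohort(path) -> pd.DataFrame:
    """Read a delimited cohort table (comma delimiter, header row)."""
    return pd.read_csv(path)


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_result(result: MorphometryResult, path) -> None:
    """Write one measurement as JSON (``.json``) or a one-row CSV."""
    path = Path(path)
    record = result.as_dict()
    if path.suffix.lower() == ".json":
        payload = dict(record, diagnostics=result.diagnostics, units={
            "neck_shaft_angle": "deg", "hhh": "mm", "asd": "mm",
            "hhd": "mm", "medial_offset": "mm",
        })
        path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    else:
        pd.DataFrame([record]).to_csv(path, index=False)


def write_ground_truth(truth, path) -> None:
    """Serialise a synthetic-anatomy ground truth object as JSON."""
    payload = dict(truth.parameters())
    payload.update(
        apex=[float(v) for v in truth.apex],
        sphere_center=[float(v) for v in truth.sphere_center],
        circle_center=[float(v) for v in truth.circle_center],
        circle_radius=float(truth.circle_radius),
        shaft_axis={"anchor": [float(v) for v in truth.shaft_axis.anchor],
                    "direction": [float(v) for v in truth.shaft_axis.direction]},
        units="mm/deg",
    )
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
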