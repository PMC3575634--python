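"""Femur data model: endosteal mesh, landmarks, anatomical frame, projections.

The canonical anatomical frame has its origin at the greater-trochanter (GT)
apex, +z along the diaphyseal shaft axis pointing distally, +y anterior, and
+x lateral. AP and lateral views are orthographic projections in this frame,
which is what makes the manufacturer entry-point rules ("GT vertex in the AP
view, anterior third in the lateral view") well defined.

Landmarks are supplied, either from a file or by the synthetic generator;
automatic landmark detection is out of scope. The shaft axis is the
total-least-squares line through the supplied shaft-axis points.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import DegenerateFrameError, MeshIntegrityError, SchemaError
from .mesh import TriMesh, load_mesh, save_mesh
from .transforms import RigidTransform, unit

log = logging.getLogger(__name__)

_LANDMARK_KEYS = ("gt_apex", "head_center", "shaft_axis_points", "anterior_dir")


@dataclass
class Landmarks:
    """Anatomical landmarks, mm, in the mesh's coordinate system.

    ``neck_base`` (optional) is the intersection of the neck axis with the
    shaft axis; the synthetic generator emits it so the neck-shaft angle can
    be re-estimated from landmarks alone.
    """

    gt_apex: np.ndarray
    head_center: np.ndarray
    shaft_axis_points: np.ndarray
    anterior_dir: np.ndarray
    side: str = "R"
    neck_base: np.ndarray | None = None

    def __post_init__(self):
        self.gt_apex = np.asarray(self.gt_apex, dtype=float).reshape(3)
        self.head_center = np.asarray(self.head_center, dtype=float).reshape(3)
        self.shaft_axis_points = np.atleast_2d(
            np.asarray(self.shaft_axis_points, dtype=float))
        self.anterior_dir = np.asarray(self.anterior_dir, dtype=float).reshape(3)
        if self.neck_base is not None:
            self.neck_base = np.asarray(self.neck_base, dtype=float).reshape(3)
        if self.side not in ("L", "R"):
            raise SchemaError(f"side must be 'L' or 'R', got {self.side!r}")
        if abs(np.linalg.norm(self.anterior_dir) - 1.0) > 1e-6:
            raise SchemaError("anterior_dir must be unit-norm")
        if len(self.shaft_axis_points) < 2:
            raise SchemaError("need >= 2 shaft_axis_points")
        span = np.linalg.norm(self.shaft_axis_points.max(0)
                              - self.shaft_axis_points.min(0))
        if span < 50.0:
            raise SchemaError(f"shaft_axis_points span {span:.1f} mm < 50 mm")
        if np.linalg.norm(self.head_center - self.gt_apex) < 1e-6:
            raise SchemaError("head_center coincides with gt_apex")

    def transformed(self, rt: RigidTransform) -> "Landmarks":
        return Landmarks(rt.apply(self.gt_apex), rt.apply(self.head_center),
                         rt.apply(self.shaft_axis_points),
                         rt.apply_vector(self.anterior_dir), self.side,
                         None if self.neck_base is None else rt.apply(self.neck_base))

    def scaled(self, k: float) -> "Landmarks":
        return Landmarks(self.gt_apex * k, self.head_center * k,
                         self.shaft_axis_points * k, self.anterior_dir,
                         self.side,
                         None if self.neck_base is None else self.neck_base * k)

    def to_dict(self) -> dict:
        d = {"gt_apex": self.gt_apex.tolist(),
             "head_center": self.head_center.tolist(),
             "shaft_axis_points": self.shaft_axis_points.tolist(),
             "anterior_dir": self.anterior_dir.tolist(),
             "side": self.side}
        if self.neck_base is not None:
            d["neck_base"] = self.neck_base.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Landmarks":
        missing = [k for k in _LANDMARK_KEYS if k not in d]
        if missing:
            raise SchemaError(f"landmark file missing keys: {missing}")
        return cls(d["gt_apex"], d["head_center"], d["shaft_axis_points"],
                   d["anterior_dir"], d.get("side", "R"), d.get("neck_base"))


@dataclass(frozen=True)
class FemurFrame:
    """Right-handed anatomical frame at the GT apex (for right femora; a
    left-side flag flips the lateral axis, see :func:`canonical_frame`)."""

    origin: np.ndarray
    x_axis: np.ndarray   # lateral
    y_axis: np.ndarray   # anterior
    z_axis: np.ndarray   # distal along shaft

    def to_frame(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float) - self.origin
        return p @ np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)

    def from_frame(self, coords) -> np.ndarray:
        c = np.asarray(coords, dtype=float)
        basis = np.stack([self.x_axis, self.y_axis, self.z_axis], axis=0)
        return c @ basis + self.origin

    def to_frame_vector(self, vectors) -> np.ndarray:
        return np.asarray(vectors, float) @ np.stack(
            [self.x_axis, self.y_axis, self.z_axis], axis=1)


def fit_line_tls(points: np.ndarray):
    """Total-least-squares line fit: returns (centroid, unit direction)."""
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    _, _, vt = np.linalg.svd(p - c, full_matrices=False)
    return c, vt[0]


def canonical_frame(landmarks: Landmarks) -> FemurFrame:
    """Anatomical frame from landmarks.

    z = TLS shaft-axis direction oriented distally (away from the GT apex);
    y = anterior_dir orthogonalized against z; x = y × z for a right femur,
    flipped for a left one. Deterministic for fixed landmarks.
    """
    centroid, d = fit_line_tls(landmarks.shaft_axis_points)
    if np.dot(centroid - landmarks.gt_apex, d) < 0:
        d = -d
    y = landmarks.anterior_dir - np.dot(landmarks.anterior_dir, d) * d
    ny = np.linalg.norm(y)
    if ny < 1e-8:
        raise DegenerateFrameError("anterior_dir is parallel to the shaft axis")
    y = y / ny
    x = np.cross(y, d)
    if landmarks.side == "L":
        x = -x
    return FemurFrame(origin=landmarks.gt_apex.copy(), x_axis=x, y_axis=y,
                      z_axis=d)


def project(point, view: str, frame: FemurFrame) -> np.ndarray:
    """Project a point to a 2-D view: AP drops the anteroposterior (y)
    coordinate → (x, z); LATERAL drops x → (y, z)."""
    c = frame.to_frame(point)
    c = np.atleast_2d(c)
    v = view.upper()
    if v == "AP":
        out = c[:, [0, 2]]
    elif v == "LATERAL":
        out = c[:, [1, 2]]
    else:
        raise SchemaError(f"unknown view {view!r}; use 'AP' or 'LATERAL'")
    return out[0] if np.asarray(point).ndim == 1 else out


@dataclass
class FemurModel:
    """Watertight endosteal (inner-cortex) surface plus landmarks and frame."""

    endosteal_mesh: TriMesh
    landmarks: Landmarks
    id: str = "femur"
    frame: FemurFrame = field(init=False)

    def __post_init__(self):
        self.endosteal_mesh.require_watertight(f"femur {self.id!r} endosteal mesh")
        self.frame = canonical_frame(self.landmarks)
        # GT apex must sit at the proximal extremity of the mesh
        z = self.endosteal_mesh.vertices @ self.frame.z_axis
        apex_z = float(self.landmarks.gt_apex @ self.frame.z_axis)
        if apex_z - z.min() > 5.0:
            raise MeshIntegrityError(
                f"gt_apex is {apex_z - z.min():.1f} mm distal of the mesh's "
                "proximal extremity (limit 5 mm)")

    def transformed(self, rt: RigidTransform, new_id: str | None = None
                    ) -> "FemurModel":
        return FemurModel(self.endosteal_mesh.transformed(rt),
                          self.landmarks.transformed(rt),
                          new_id or self.id)

    def scaled(self, k: float, new_id: str | None = None) -> "FemurModel":
        return FemurModel(self.endosteal_mesh.scaled(k),
                          self.landmarks.scaled(k), new_id or self.id)


def load_femur(mesh_path, landmarks_path, femur_id: str | None = None
               ) -> FemurModel:
    """Load an STL/PLY endosteal mesh and a JSON/YAML landmark file.

    Mesh files carry no unit metadata; coordinates are assumed to be mm
    (a warning is logged).
    """
    mesh_path, landmarks_path = Path(mesh_path), Path(landmarks_path)
    mesh = load_mesh(mesh_path)
    log.warning("assuming mesh units are mm for %s", mesh_path.name)
    text = Path(landmarks_path).read_text()
    if landmarks_path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise SchemaError("landmark file must contain a mapping")
    lm = Landmarks.from_dict(data)
    return FemurModel(mesh, lm, femur_id or mesh_path.stem)


def save_femur(model: FemurModel, mesh_path, landmarks_path,
               binary_stl: bool = False) -> None:
    save_mesh(model.endosteal_mesh, mesh_path, binary_stl=binary_stl)
    Path(landmarks_path).write_text(
        json.dumps(model.landmarks.to_dict(), indent=1))
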