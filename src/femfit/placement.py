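"""Virtual nail insertion following the manufacturer placement rules.

The rules fix everything except two degrees of freedom:

* the entry point is at the GT vertex in the AP view and at the boundary of
  the anterior and middle thirds of the trochanteric AP extent in the
  lateral view;
* the nail's proximal segment passes through the entry point aligned with
  the local proximal canal direction (default: the canal chord over the
  span the nail occupies — a rigid nail self-aligns within that corridor);
* the remaining freedoms — insertion depth along that axis and axial
  rotation about it — are solved deterministically so that the head-element
  axis passes through the center of the femoral head ("the antirotation
  screw in the middle of the femoral head", which also determines the depth
  of insertion).

The solver is a coarse grid search (1 mm × 1°) refined to 0.01 mm / 0.01°,
ties broken toward smaller depth then smaller rotation. Placement is rigid:
penetration of the cortex is permitted (and measured downstream) — the
rule-based position is never relaxed to avoid impingement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .femur import FemurModel
from .nails import NailMesh
from .transforms import RigidTransform, rotation_about_axis

#: proximal band used to measure the local trochanteric AP extent for the
#: lateral-view rule, as a fraction of the mesh's proximodistal extent
#: (≈5 mm for an adult femur; relative so the rule is scale-equivariant)
_TROCH_BAND_FRACTION = 0.012


@dataclass(frozen=True)
class PlacementOptions:
    """Solver settings (mm / degrees)."""

    depth_range: tuple = (-20.0, 40.0)   # proximal-tip offset below entry plane
    depth_step: float = 1.0
    rotation_step: float = 1.0
    refine_depth_tol: float = 0.01
    refine_rotation_tol: float = 0.01
    tol: float = 1.0                     # head-center miss for convergence
    give_up_miss: float = 10.0
    approach_angle: float = 0.0          # trochanteric approach tilt, degrees
    direction_window: float | None = None  # canal span for the insertion
                                           # direction; None = nail length

    def scaled(self, k: float) -> "PlacementOptions":
        return PlacementOptions(
            (self.depth_range[0] * k, self.depth_range[1] * k),
            self.depth_step * k, self.rotation_step,
            self.refine_depth_tol * k, self.refine_rotation_tol,
            self.tol * k, self.give_up_miss * k, self.approach_angle,
            None if self.direction_window is None
            else self.direction_window * k)


@dataclass
class PlacementResult:
    """Rigid transform (nail-local → femur world) realizing the rules."""

    transform: RigidTransform
    entry_point: np.ndarray
    insertion_depth: float       # arc length of nail distal of the entry plane
    tip_offset: float            # proximal tip below (+) / above (−) entry plane
    rotation_deg: float
    head_center_miss: float
    converged: bool

    def to_dict(self) -> dict:
        return {"transform": self.transform.matrix.reshape(-1).tolist(),
                "entry_point": self.entry_point.tolist(),
                "insertion_depth": self.insertion_depth,
                "tip_offset": self.tip_offset,
                "rotation_deg": self.rotation_deg,
                "head_center_miss": self.head_center_miss,
                "converged": bool(self.converged)}


def entry_point(femur: FemurModel) -> np.ndarray:
    """Manufacturer-rule entry point on the proximal surface (world mm).

    AP view: coincides with the GT apex. Lateral view: at the boundary
    between the anterior and middle thirds of the local trochanteric AP
    extent, i.e. y = y_min + (2/3)(y_max − y_min) measured from posterior.
    """
    frame = femur.frame
    c = frame.to_frame(femur.endosteal_mesh.vertices)
    z_min = c[:, 2].min()
    band_width = _TROCH_BAND_FRACTION * np.ptp(c[:, 2])
    band = c[c[:, 2] <= z_min + band_width]
    if len(band) < 3:
        raise GeometryError("cannot locate the proximal trochanteric surface")
    y_min, y_max = band[:, 1].min(), band[:, 1].max()
    y_entry = y_min + (2.0 / 3.0) * (y_max - y_min)
    # drop a distally-directed ray onto the surface at the target AP position
    origin = frame.from_frame(np.array([0.0, y_entry, z_min - 50.0]))
    t = femur.endosteal_mesh.ray_first_hit(origin[None, :], frame.z_axis)[0]
    if not np.isfinite(t):
        raise GeometryError("entry ray misses the proximal surface")
    return origin + t * frame.z_axis


def canal_corridor_direction(femur: FemurModel, entry: np.ndarray,
                             window: float = 170.0,
                             bin_width: float | None = None) -> np.ndarray:
    """Insertion corridor direction for a nail occupying ``window`` mm of
    canal below ``entry`` (unit, distal-pointing, world coordinates).

    The canal axis is estimated as per-bin centroids of mesh vertices along
    the frame z-axis, skipping the metaphyseal segment whose cross-sections
    are not canal-like. The two anatomical planes are treated differently,
    mirroring how the implant is meant to be used:

    * frontal (x–z) slope: parallel to the canal axis — the nail's
      mediolateral bend, not the insertion angle, absorbs the lateral offset
      of the trochanteric entry point;
    * sagittal (y–z) slope: aimed from the entry point at the canal axis one
      window-length down — a rigid, sagittally straight nail chords the
      anterior bow of the shaft.

    For a straight canal entered on its axis this reduces to the shaft axis.
    """
    frame = femur.frame
    c = frame.to_frame(femur.endosteal_mesh.vertices)
    z = c[:, 2]
    e = frame.to_frame(entry)
    z1 = min(e[2] + window, z.max() - 0.04 * window)
    # both the metaphyseal skip and the bin width are relative to the
    # corridor length so the whole construction is scale-equivariant
    skip = 0.25 * (z1 - e[2])
    if bin_width is None:
        bin_width = (z1 - e[2]) / 16.0
    edges = np.arange(e[2] + skip, z1 + 1e-9, bin_width)
    cents = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (z >= lo) & (z < hi)
        if m.sum() >= 6:
            cents.append(c[m].mean(axis=0))
    if len(cents) < 2:
        raise GeometryError("cannot estimate the canal corridor direction")
    cents = np.asarray(cents)
    # frontal slope: least-squares x(z) over the canal bins
    A = np.stack([np.ones(len(cents)), cents[:, 2]], axis=1)
    sx = float(np.linalg.lstsq(A, cents[:, 0], rcond=None)[0][1])
    # sagittal slope: chord from the entry to the far end of the corridor
    far = cents[-1]
    sy = float((far[1] - e[1]) / (far[2] - e[2]))
    d = np.array([sx, sy, 1.0])
    d /= np.linalg.norm(d)
    world = d @ np.stack([frame.x_axis, frame.y_axis, frame.z_axis], axis=0)
    return world / np.linalg.norm(world)


def _insertion_axes(femur: FemurModel, entry: np.ndarray,
                    opts: PlacementOptions, window: float = 170.0):
    """Insertion direction and base rotation (nail axes → femur axes)."""
    frame = femur.frame
    z_dir = canal_corridor_direction(
        femur, entry,
        opts.direction_window if opts.direction_window else window)
    if opts.approach_angle:
        z_dir = rotation_about_axis(frame.y_axis,
                                    math.radians(opts.approach_angle)) @ z_dir
    x_dir = frame.x_axis - (frame.x_axis @ z_dir) * z_dir
    x_dir = x_dir / np.linalg.norm(x_dir)
    y_dir = np.cross(z_dir, x_dir)
    base_rot = np.stack([x_dir, y_dir, z_dir], axis=1)
    return z_dir, base_rot


def solve_depth_rotation(femur: FemurModel, nail: NailMesh, entry: np.ndarray,
                         opts: PlacementOptions = PlacementOptions()):
    """Global grid minimizer of the head-center miss over (depth, rotation).

    Returns ``(depth, rotation_deg, miss)``. Deterministic; the coarse grid
    (``depth_step`` × ``rotation_step``) is refined locally to the stated
    tolerances, ties broken toward smaller depth then smaller rotation.
    """
    lo, hi = opts.depth_range
    if lo >= hi:
        raise GeometryError(f"empty feasible depth range [{lo}, {hi}]")
    z_dir, base_rot = _insertion_axes(femur, entry, opts, nail.total_length)
    head = femur.landmarks.head_center
    h0 = float(nail.head_axis_point[2])          # on the proximal axis segment
    u0 = nail.head_axis_dir

    def miss_grid(depths, rots_deg):
        """(len(depths), len(rots)) head-center miss surface."""
        anchors = entry[None, :] + (depths[:, None] + h0) * z_dir[None, :]
        w = head[None, :] - anchors                              # (D, 3)
        phis = np.radians(rots_deg)
        cos_p, sin_p = np.cos(phis), np.sin(phis)
        # u(phi) = base_rot @ Rz(phi) @ u0
        ux = cos_p * u0[0] - sin_p * u0[1]
        uy = sin_p * u0[0] + cos_p * u0[1]
        u = (np.outer(ux, base_rot[:, 0]) + np.outer(uy, base_rot[:, 1])
             + u0[2] * base_rot[:, 2][None, :])                  # (R, 3)
        w_dot_u = w @ u.T                                        # (D, R)
        w_sq = (w ** 2).sum(axis=1)[:, None]
        return np.sqrt(np.maximum(w_sq - w_dot_u ** 2, 0.0))

    def best(depths, rots_deg):
        m = miss_grid(depths, rots_deg)
        di, ri = np.meshgrid(np.arange(len(depths)), np.arange(len(rots_deg)),
                             indexing="ij")
        keys = np.lexsort((rots_deg[ri.ravel()], depths[di.ravel()],
                           np.round(m.ravel(), 9)))
        k = keys[0]
        return depths[di.ravel()[k]], rots_deg[ri.ravel()[k]], m.ravel()[k]

    depths = np.arange(lo, hi + 0.5 * opts.depth_step, opts.depth_step)
    rots = np.arange(0.0, 360.0, opts.rotation_step)
    d0, r0, _ = best(depths, rots)
    fine_d = np.arange(max(lo, d0 - opts.depth_step),
                       min(hi, d0 + opts.depth_step) + 1e-9,
                       opts.refine_depth_tol)
    fine_r = np.round(np.arange(r0 - opts.rotation_step,
                                r0 + opts.rotation_step + 1e-9,
                                opts.refine_rotation_tol) % 360.0, 10)
    d1, r1, m1 = best(fine_d, fine_r)
    return float(d1), float(r1 % 360.0), float(m1)


def place_nail(femur: FemurModel, nail: NailMesh,
               opts: PlacementOptions = PlacementOptions()) -> PlacementResult:
    """Insert ``nail`` into ``femur`` per the manufacturer rules."""
    entry = entry_point(femur)
    depth, rot, miss = solve_depth_rotation(femur, nail, entry, opts)
    z_dir, base_rot = _insertion_axes(femur, entry, opts, nail.total_length)
    R = base_rot @ rotation_about_axis(np.array([0.0, 0.0, 1.0]),
                                       math.radians(rot))
    t = entry + depth * z_dir
    transform = RigidTransform(R, t)
    L = nail.total_length
    inserted = L - max(0.0, -depth)
    return PlacementResult(transform=transform, entry_point=entry,
                           insertion_depth=float(inserted),
                           tip_offset=depth, rotation_deg=rot,
                           head_center_miss=miss,
                           converged=bool(miss <= opts.tol))
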