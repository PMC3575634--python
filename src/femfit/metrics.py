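"""Geometric fitness parameters of a placed nail.

Eight quantities (A–H) characterize how a rule-placed nail fits the
medullary canal:

=====  =============================================================
A      greatest penetration thickness into the inner cortex, proximal
B      average axial length of proximal impingement patches
C      distance from the proximal patch center to the GT apex
D      length of the nail protruding beyond the GT apex plane
E      maximum thickness / length of mid-shaft impingement
F      distance from the mid-shaft patch center to the GT apex
G      maximum anterior gap between nail and inner cortex, mid-shaft
H      axial length of impingement at the distal part of the nail
=====  =============================================================

Penetration is the signed distance from nail-surface samples to the
endosteal surface (positive = outside the canal volume, i.e. protruding
into cortex). Impingement patches are connected components of over-threshold
samples; "thickness" is the maximum penetration depth normal to the
endosteal surface. Regions are nail-relative: proximal up to the bend
station (+margin), distal the last quarter of the inserted length, middle
the remainder.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import GeometryError
from .femur import FemurFrame, FemurModel
from .nails import NailMesh, NailSpec, axis_path, sample_surface
from .placement import PlacementResult

log = logging.getLogger(__name__)

REGIONS = ("proximal", "middle", "distal")
SIDES = ("anterior", "posterior", "lateral", "medial")


@dataclass(frozen=True)
class FitnessOptions:
    """Measurement settings (mm unless noted)."""

    density: float = 4.0              # nail-surface samples per mm^2, minimum
    threshold: float = 0.1            # impingement depth threshold
    linkage_radius: float = 2.0       # patch connectivity radius
    proximal_margin: float = 10.0     # proximal region extends to bend+margin
    distal_fraction: float = 0.25     # distal region share of inserted length
    allow_unconverged: bool = False
    distance_mode: str = "euclidean"  # or "along_axis" for C/F

    def scaled(self, k: float) -> "FitnessOptions":
        """Options for a scene scaled by ``k`` (same sampling topology)."""
        return replace(self, density=self.density / k ** 2,
                       threshold=self.threshold * k,
                       linkage_radius=self.linkage_radius * k,
                       proximal_margin=self.proximal_margin * k)


@dataclass
class PenetrationField:
    """Signed penetration depths of nail-surface samples (femur world mm)."""

    points: np.ndarray        # (n, 3) sample positions
    depth: np.ndarray         # (n,) signed mm, positive = into cortex
    station: np.ndarray       # (n,) arc length along the nail axis
    in_bone: np.ndarray       # (n,) bool, sample distal of the entry plane
    axis_points: np.ndarray   # (k, 3) placed nail axis polyline
    axis_stations: np.ndarray
    frame: FemurFrame
    placement: PlacementResult
    spec: NailSpec


@dataclass
class ImpingementPatch:
    """One connected penetration region on the nail surface."""

    member_idx: np.ndarray
    max_thickness: float
    axial_length: float
    centroid: np.ndarray
    station_centroid: float
    axis_point: np.ndarray        # closest placed-axis point to the centroid
    dist_to_gt_apex: float
    region: str | None = None
    side: str | None = None

    @property
    def n_samples(self) -> int:
        return len(self.member_idx)


def penetration_field(femur: FemurModel, nail: NailMesh,
                      placement: PlacementResult,
                      opts: FitnessOptions = FitnessOptions()
                      ) -> PenetrationField:
    """Signed distance of dense nail-surface samples to the endosteal wall.

    Samples proximal of the entry plane are flagged ``in_bone=False`` and
    excluded from patch extraction (they are protrusion, not impingement).
    """
    if not placement.converged and not opts.allow_unconverged:
        raise GeometryError(
            f"placement did not converge (miss {placement.head_center_miss:.1f} "
            "mm); pass allow_unconverged to measure anyway")
    femur.endosteal_mesh.require_watertight("endosteal mesh")
    local_pts, stations = sample_surface(nail.spec, density=opts.density,
                                         bend_radius=nail.bend_radius)
    world = placement.transform.apply(local_pts)
    depth = femur.endosteal_mesh.signed_distance(world)
    entry_z = float(femur.frame.to_frame(placement.entry_point)[2])
    in_bone = femur.frame.to_frame(world)[:, 2] >= entry_z - 1e-9
    ax_local, _, _ = axis_path(nail.spec, nail.axis_stations, nail.bend_radius)
    return PenetrationField(points=world, depth=depth, station=stations,
                            in_bone=in_bone,
                            axis_points=placement.transform.apply(ax_local),
                            axis_stations=nail.axis_stations,
                            frame=femur.frame, placement=placement,
                            spec=nail.spec)


def extract_patches(field: PenetrationField, threshold: float = 0.1,
                    linkage_radius: float = 2.0) -> list[ImpingementPatch]:
    """Connected components of over-threshold samples.

    Two samples are linked when closer than ``linkage_radius``. Patch
    thickness is the maximum member depth; axial length is the station
    extent. Returns an empty list when nothing penetrates.
    """
    idx = np.nonzero((field.depth > threshold) & field.in_bone)[0]
    if len(idx) == 0:
        return []
    pts = field.points[idx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(linkage_radius, output_type="ndarray")
    n = len(idx)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    apex = field.frame.origin
    patches = []
    for comp in range(n_comp):
        mem = idx[labels == comp]
        centroid = field.points[mem].mean(axis=0)
        st = field.station[mem]
        d_axis = np.linalg.norm(field.axis_points - centroid, axis=1)
        patches.append(ImpingementPatch(
            member_idx=mem,
            max_thickness=float(field.depth[mem].max()),
            axial_length=float(st.max() - st.min()),
            centroid=centroid,
            station_centroid=float(st.mean()),
            axis_point=field.axis_points[int(np.argmin(d_axis))],
            dist_to_gt_apex=float(np.linalg.norm(centroid - apex))))
    patches.sort(key=lambda p: p.station_centroid)
    return patches


def region_boundaries(spec: NailSpec, placement: PlacementResult,
                      opts: FitnessOptions = FitnessOptions()) -> dict:
    """Nail-relative region boundaries (stations, mm from the proximal tip)."""
    s0 = max(0.0, -placement.tip_offset)        # station at the entry plane
    inserted = spec.total_length - s0
    return {"proximal_end": spec.bend_station + opts.proximal_margin,
            "distal_start": s0 + (1.0 - opts.distal_fraction) * inserted,
            "entry_station": s0}


def classify_region(patch: ImpingementPatch, boundaries: dict) -> str:
    """Assign proximal/middle/distal by centroid station; boundary ties go
    to the more proximal region."""
    s = patch.station_centroid
    if s <= boundaries["proximal_end"]:
        return "proximal"
    if s <= boundaries["distal_start"]:
        return "middle"
    return "distal"


def classify_side(patch: ImpingementPatch, frame: FemurFrame) -> str:
    """90°-sector side of the patch centroid around the local canal axis.

    Sectors are centered on +y (anterior), −y (posterior), +x (lateral) and
    −x (medial); exact 45° boundaries break toward the mediolateral (x)
    sector.
    """
    v = frame.to_frame_vector(patch.centroid - patch.axis_point)
    x, y = float(v[0]), float(v[1])
    if math.hypot(x, y) < 1e-9:
        raise GeometryError("patch centroid lies on the canal axis")
    if abs(x) >= abs(y):
        return "lateral" if x > 0 else "medial"
    return "anterior" if y > 0 else "posterior"


def protrusion_length(nail: NailMesh, placement: PlacementResult,
                      frame: FemurFrame) -> float:
    """Length of nail proximal tip above the GT-apex transverse plane (D)."""
    tip_world = placement.transform.apply(np.zeros(3))
    z = float(frame.to_frame(tip_world)[2])
    return max(0.0, -z)


@dataclass
class GapResult:
    max_anterior_gap: float | None
    station_at_max: float | None
    max_clearance: float | None      # all-direction, for comparison
    n_stations: int


def max_gap_middle(femur: FemurModel, field: PenetrationField,
                   boundaries: dict) -> GapResult:
    """Maximum anterior gap between nail and inner cortex in the mid-shaft.

    For each sampled station in the middle region, a ray is cast from the
    nail's anterior-most surface point along +y (anterior) in that station's
    sagittal plane; the gap is the distance to the endosteal surface.
    Stations whose ray misses the mesh are excluded with a logged warning.
    """
    mid = (field.in_bone & (field.station > boundaries["proximal_end"])
           & (field.station <= boundaries["distal_start"]))
    if not mid.any():
        return GapResult(None, None, None, 0)
    coords = femur.frame.to_frame(field.points)
    stations = np.unique(field.station[mid])
    origins = np.empty((len(stations), 3))
    for i, s in enumerate(stations):
        ring = np.nonzero(mid & (field.station == s))[0]
        origins[i] = field.points[ring[np.argmax(coords[ring, 1])]]
    t = femur.endosteal_mesh.ray_first_hit(origins, femur.frame.y_axis)
    ok = np.isfinite(t)
    if (~ok).any():
        log.warning("%d/%d anterior gap rays missed the endosteal surface",
                    int((~ok).sum()), len(t))
    if not ok.any():
        return GapResult(None, None, None, 0)
    k = int(np.argmax(np.where(ok, t, -np.inf)))
    clearance = float(max(0.0, -(field.depth[mid]).min()))
    return GapResult(max_anterior_gap=float(t[k]),
                     station_at_max=float(stations[k]),
                     max_clearance=clearance, n_stations=int(ok.sum()))


@dataclass
class FitnessReport:
    """Per-specimen record of the fitness parameters A–H (mm).

    Metrics of a region with no impingement are ``None`` (never 0); G and D
    are defined for every specimen.
    """

    femur_id: str
    nail_id: str
    A_max_thickness_proximal: float | None = None
    B_length_proximal: float | None = None
    C_dist_proximal: float | None = None
    D_protrusion: float = 0.0
    E_thickness_middle: float | None = None
    E_length_middle: float | None = None
    F_dist_middle: float | None = None
    G_max_gap_middle: float | None = None
    H_length_distal: float | None = None
    impinged: dict = field(default_factory=lambda: dict.fromkeys(REGIONS, False))
    side: dict = field(default_factory=lambda: dict.fromkeys(REGIONS, None))
    boundaries: dict = field(default_factory=dict)
    n_patches: int = 0
    converged: bool = True
    head_center_miss: float | None = None
    insertion_depth: float | None = None

    _FLOATS = ("A_max_thickness_proximal", "B_length_proximal",
               "C_dist_proximal", "D_protrusion", "E_thickness_middle",
               "E_length_middle", "F_dist_middle", "G_max_gap_middle",
               "H_length_distal")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("femur_id", "nail_id", *self._FLOATS, "impinged", "side",
              "boundaries", "n_patches", "converged", "head_center_miss",
              "insertion_depth")}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessReport":
        import dataclasses
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_json(cls, s: str) -> "FitnessReport":
        return cls.from_dict(json.loads(s))


def compute_fitness(femur: FemurModel, nail: NailMesh,
                    placement: PlacementResult,
                    opts: FitnessOptions = FitnessOptions(),
                    field_: PenetrationField | None = None) -> FitnessReport:
    """Assemble the full A–H fitness report for one placed nail."""
    fld = field_ if field_ is not None else penetration_field(
        femur, nail, placement, opts)
    bounds = region_boundaries(nail.spec, placement, opts)
    patches = extract_patches(fld, opts.threshold, opts.linkage_radius)
    by_region: dict[str, list[ImpingementPatch]] = {r: [] for r in REGIONS}
    for p in patches:
        p.region = classify_region(p, bounds)
        p.side = classify_side(p, femur.frame)
        by_region[p.region].append(p)

    report = FitnessReport(femur_id=femur.id, nail_id=nail.spec.model_id.value,
                           boundaries=bounds, n_patches=len(patches),
                           converged=placement.converged,
                           head_center_miss=placement.head_center_miss,
                           insertion_depth=placement.insertion_depth)
    apex = femur.frame.origin

    def patch_distance(p: ImpingementPatch) -> float:
        if opts.distance_mode == "along_axis":
            return float(p.station_centroid - bounds["entry_station"])
        return p.dist_to_gt_apex

    for region in REGIONS:
        ps = by_region[region]
        report.impinged[region] = bool(ps)
        if not ps:
            continue
        thickest = max(ps, key=lambda p: p.max_thickness)
        report.side[region] = thickest.side
        mean_len = float(np.mean([p.axial_length for p in ps]))
        if region == "proximal":
            report.A_max_thickness_proximal = thickest.max_thickness
            report.B_length_proximal = mean_len
            report.C_dist_proximal = patch_distance(thickest)
        elif region == "middle":
            report.E_thickness_middle = thickest.max_thickness
            report.E_length_middle = mean_len
            report.F_dist_middle = patch_distance(thickest)
        else:
            report.H_length_distal = mean_len

    report.D_protrusion = protrusion_length(nail, placement, femur.frame)
    gap = max_gap_middle(femur, fld, bounds)
    report.G_max_gap_middle = gap.max_anterior_gap
    return report
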