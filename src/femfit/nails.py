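"""Parametric cephalomedullary-nail geometry.

A nail is described by a :class:`NailSpec` (lengths, diameters, mediolateral
bend, head-element angle, proximal cross-section shape) and realized as a
watertight surface mesh swept along its axis polyline. Supported designs:

* ``PFNA2`` — helical-blade nail for Asian femora: 5° mediolateral bend,
  16.5 mm proximal diameter, flattened lateral face at the proximal portion;
* ``PFNA`` (legacy comparator) — 6° bend, 17 mm proximal diameter, circular;
* ``INTERTAN`` — integrated twin-screw nail with a trapezoidal proximal
  cross-section;
* ``GENERIC`` — plain circular nail for constructed test geometries.

Nail-local frame: origin at the proximal tip, +z toward the distal tip along
the proximal segment, +x toward the lateral (flat) face, +y anterior. The
bend is a circular-arc transition (default radius 50 mm) in the x–z plane
tilting the distal segment medially (−x). The head element (blade / screw
pair) is modeled as an axis plus cylindrical envelope only; thread and blade
micro-geometry are out of scope.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .errors import GeometryError, InvalidSpecError
from .mesh import TriMesh, mesh_from_rings


class NailModel(str, enum.Enum):
    PFNA2 = "PFNA2"
    PFNA = "PFNA"
    INTERTAN = "INTERTAN"
    GENERIC = "GENERIC"


class ProximalSection(str, enum.Enum):
    CIRCULAR = "circular"
    FLAT_LATERAL = "flat_lateral"
    TRAPEZOIDAL = "trapezoidal"


# Representative catalog/config defaults for quantities the designs do not pin
# down numerically. Every experiment records the resolved spec, so these are
# overridable, documented assumptions — never hard-coded inside operations.
NAIL_DEFAULTS: dict = {
    "pfna2": dict(proximal_diameter=16.5, bend_angle=5.0, bend_station=90.0,
                  ccd_angle=130.0, proximal_section="flat_lateral",
                  flat_depth=1.5, trapezoid_ap_depth=0.0,
                  head_element_length=100.0),
    "pfna": dict(proximal_diameter=17.0, bend_angle=6.0, bend_station=90.0,
                 ccd_angle=130.0, proximal_section="circular",
                 flat_depth=0.0, trapezoid_ap_depth=0.0,
                 head_element_length=100.0),
    "intertan": dict(proximal_diameter=16.25, bend_angle=4.0, bend_station=85.0,
                     ccd_angle=130.0, proximal_section="trapezoidal",
                     flat_depth=0.0, trapezoid_ap_depth=15.0,
                     head_element_length=100.0, twin_screws=True),
}

#: arc radius of the bend transition between straight segments (mm)
DEFAULT_BEND_RADIUS = 50.0
#: arc-length station where the head-element axis crosses the nail axis (mm)
DEFAULT_HEAD_STATION = 40.0
#: AP half-width ratio of the medial vs lateral face of the trapezoid section
TRAPEZOID_MEDIAL_RATIO = 0.7


@dataclass(frozen=True)
class NailSpec:
    """Parametric description of an intramedullary nail (all lengths mm,
    angles degrees)."""

    model_id: NailModel
    total_length: float
    proximal_diameter: float
    distal_diameter: float
    bend_angle: float
    bend_station: float
    ccd_angle: float
    proximal_section: ProximalSection
    flat_depth: float = 0.0
    trapezoid_ap_depth: float = 0.0
    head_element_length: float = 100.0
    twin_screws: bool = False

    def __post_init__(self):
        object.__setattr__(self, "model_id", NailModel(self.model_id))
        object.__setattr__(self, "proximal_section",
                           ProximalSection(self.proximal_section))
        if not (self.total_length > self.bend_station > 0):
            raise InvalidSpecError(
                f"need total_length > bend_station > 0, got "
                f"{self.total_length} / {self.bend_station}")
        if not (self.proximal_diameter >= self.distal_diameter > 0):
            raise InvalidSpecError(
                f"need proximal_diameter >= distal_diameter > 0, got "
                f"{self.proximal_diameter} / {self.distal_diameter}")
        if not (0 <= self.bend_angle < 15):
            raise InvalidSpecError(f"bend_angle out of [0, 15): {self.bend_angle}")
        if not (90 < self.ccd_angle < 180):
            raise InvalidSpecError(f"ccd_angle out of (90, 180): {self.ccd_angle}")
        sec = self.proximal_section
        if sec is not ProximalSection.FLAT_LATERAL and self.flat_depth != 0:
            raise InvalidSpecError("flat_depth must be 0 unless flat_lateral")
        if sec is not ProximalSection.TRAPEZOIDAL and self.trapezoid_ap_depth != 0:
            raise InvalidSpecError("trapezoid_ap_depth must be 0 unless trapezoidal")
        if sec is ProximalSection.FLAT_LATERAL and not (
                0 < self.flat_depth < self.proximal_diameter / 2):
            raise InvalidSpecError("flat_depth must be in (0, proximal radius)")
        if sec is ProximalSection.TRAPEZOIDAL and not (
                0 < self.trapezoid_ap_depth <= self.proximal_diameter):
            raise InvalidSpecError("trapezoid_ap_depth out of range")
        if self.head_element_length <= 0:
            raise InvalidSpecError("head_element_length must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_id"] = self.model_id.value
        d["proximal_section"] = self.proximal_section.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NailSpec":
        return cls(**d)

    def scaled(self, k: float) -> "NailSpec":
        """Spec with every length multiplied by ``k`` (angles unchanged)."""
        return replace(self, total_length=self.total_length * k,
                       proximal_diameter=self.proximal_diameter * k,
                       distal_diameter=self.distal_diameter * k,
                       bend_station=self.bend_station * k,
                       flat_depth=self.flat_depth * k,
                       trapezoid_ap_depth=self.trapezoid_ap_depth * k,
                       head_element_length=self.head_element_length * k)


def _make_spec(name: str, model_id: NailModel, length: float,
               distal_diameter: float, overrides: dict) -> NailSpec:
    if length <= 0 or distal_diameter <= 0:
        raise InvalidSpecError(
            f"nail dimensions must be positive: length={length}, "
            f"distal_diameter={distal_diameter}")
    kw = dict(NAIL_DEFAULTS[name])
    kw.update(overrides)
    return NailSpec(model_id=model_id, total_length=length,
                    distal_diameter=distal_diameter, **kw)


def make_pfna2_spec(length: float, distal_diameter: float, **overrides) -> NailSpec:
    """PFNA-II-like spec: 5° bend, 16.5 mm proximal diameter, flat lateral
    face on the proximal portion."""
    return _make_spec("pfna2", NailModel.PFNA2, length, distal_diameter, overrides)


def make_pfna_legacy_spec(length: float, distal_diameter: float,
                          **overrides) -> NailSpec:
    """Original-PFNA comparator: 6° bend, 17 mm proximal diameter, circular."""
    return _make_spec("pfna", NailModel.PFNA, length, distal_diameter, overrides)


def make_intertan_spec(length: float, distal_diameter: float,
                       **overrides) -> NailSpec:
    """InterTan-like spec: trapezoidal proximal end, integrated twin-screw
    corridor. Dimensions are representative config defaults (the design's
    catalog values are not normative here) and fully overridable."""
    return _make_spec("intertan", NailModel.INTERTAN, length, distal_diameter,
                      overrides)


def make_generic_spec(length: float, diameter: float, *, bend_angle: float = 0.0,
                      ccd_angle: float = 130.0, bend_station: float | None = None,
                      **overrides) -> NailSpec:
    """Plain circular nail, handy for analytic test constructions."""
    if length <= 0 or diameter <= 0:
        raise InvalidSpecError("nail dimensions must be positive")
    kw = dict(proximal_diameter=diameter, bend_angle=bend_angle,
              bend_station=bend_station if bend_station is not None else length / 2,
              ccd_angle=ccd_angle, proximal_section="circular",
              head_element_length=max(50.0, diameter * 5))
    kw.update(overrides)
    return NailSpec(model_id=NailModel.GENERIC, total_length=length,
                    distal_diameter=diameter, **kw)


# ------------------------------------------------------------------ axis path
def axis_path(spec: NailSpec, stations: np.ndarray,
              bend_radius: float = DEFAULT_BEND_RADIUS):
    """Evaluate the nail axis at arc-length ``stations``.

    The path starts at the origin along +z, then turns by ``bend_angle``
    about +y through a circular arc centered on the bend station, tilting the
    distal segment medially (−x). Returns (points, tangents, laterals) where
    ``laterals`` is the transported +x direction (the +y direction is the
    constant anterior axis for this planar path).
    """
    s = np.asarray(stations, dtype=float)
    beta = math.radians(spec.bend_angle)
    arc_len = bend_radius * beta
    s0 = spec.bend_station - arc_len / 2.0
    s1 = spec.bend_station + arc_len / 2.0
    if beta > 0 and s0 <= 0:
        raise GeometryError("bend arc extends proximal of the nail tip")

    pts = np.zeros(s.shape + (3,))
    tan = np.zeros_like(pts)
    # proximal straight
    m0 = s <= s0
    pts[m0] = np.stack([np.zeros(m0.sum()), np.zeros(m0.sum()), s[m0]], axis=-1)
    tan[m0] = [0.0, 0.0, 1.0]
    if beta > 0:
        # arc: center at (-R, 0, s0); turn angle phi = (s - s0)/R
        ma = (s > s0) & (s < s1)
        phi = (s[ma] - s0) / bend_radius
        pts[ma] = np.stack([-bend_radius * (1 - np.cos(phi)),
                            np.zeros(ma.sum()),
                            s0 + bend_radius * np.sin(phi)], axis=-1)
        tan[ma] = np.stack([-np.sin(phi), np.zeros(ma.sum()), np.cos(phi)],
                           axis=-1)
        # distal straight
        md = s >= s1
        p1 = np.array([-bend_radius * (1 - math.cos(beta)), 0.0,
                       s0 + bend_radius * math.sin(beta)])
        d1 = np.array([-math.sin(beta), 0.0, math.cos(beta)])
        pts[md] = p1 + (s[md] - s1)[:, None] * d1
        tan[md] = d1
    else:
        m = s > s0
        pts[m] = np.stack([np.zeros(m.sum()), np.zeros(m.sum()), s[m]], axis=-1)
        tan[m] = [0.0, 0.0, 1.0]
    lat = np.cross(np.array([0.0, 1.0, 0.0]), tan)
    lat /= np.linalg.norm(lat, axis=-1, keepdims=True)
    return pts, tan, lat


def distal_direction(spec: NailSpec) -> np.ndarray:
    b = math.radians(spec.bend_angle)
    return np.array([-math.sin(b), 0.0, math.cos(b)])


def head_axis(spec: NailSpec, head_station: float = DEFAULT_HEAD_STATION):
    """Head-element axis in nail-local coordinates.

    Anchored on the proximal axis segment at ``head_station`` mm from the
    tip; direction makes ``ccd_angle`` with the distal nail axis in the
    mediolateral plane, pointing medially and proximally (toward the femoral
    head once implanted).
    """
    if head_station >= spec.bend_station:
        raise GeometryError("head_station must lie on the proximal segment")
    d = distal_direction(spec)
    b = math.radians(spec.bend_angle)
    lat = np.array([math.cos(b), 0.0, math.sin(b)])  # transported +x at distal
    ccd = math.radians(spec.ccd_angle)
    direction = math.cos(ccd) * d - math.sin(ccd) * lat
    return np.array([0.0, 0.0, head_station]), direction / np.linalg.norm(direction)


# -------------------------------------------------------------- cross sections
def _trapezoid_radial(thetas: np.ndarray, half_width: float,
                      ap_depth: float) -> np.ndarray:
    """Radial extent of a trapezoid boundary at polar angles ``thetas``.

    Corners: lateral face at x=+half_width with AP half-extent t_lat,
    medial face at x=-half_width with t_med = ratio * t_lat.
    """
    t_lat = ap_depth / 2.0
    t_med = TRAPEZOID_MEDIAL_RATIO * t_lat
    corners = np.array([[half_width, t_lat], [-half_width, t_med],
                        [-half_width, -t_med], [half_width, -t_lat]])
    c = np.cos(thetas)
    s = np.sin(thetas)
    r_out = np.full(thetas.shape, np.inf)
    for i in range(4):
        p, q = corners[i], corners[(i + 1) % 4]
        e = q - p
        denom = c * e[1] - s * e[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ray = np.where(np.abs(denom) > 1e-12,
                             (p[0] * e[1] - p[1] * e[0]) / denom, np.inf)
        u_num = np.where(np.abs(e[0]) > np.abs(e[1]),
                         (t_ray * c - p[0]) / np.where(e[0] == 0, 1, e[0]),
                         (t_ray * s - p[1]) / np.where(e[1] == 0, 1, e[1]))
        ok = (t_ray > 0) & (u_num >= -1e-9) & (u_num <= 1 + 1e-9)
        r_out = np.where(ok, np.minimum(r_out, t_ray), r_out)
    if not np.isfinite(r_out).all():
        raise GeometryError("degenerate trapezoid cross-section")
    return r_out


def cross_section(spec: NailSpec, station: float, thetas: np.ndarray,
                  bend_radius: float = DEFAULT_BEND_RADIUS) -> np.ndarray:
    """(x, y) boundary points of the cross-section at an axis station."""
    beta = math.radians(spec.bend_angle)
    arc_len = bend_radius * beta
    s0 = spec.bend_station - arc_len / 2.0
    s1 = spec.bend_station + arc_len / 2.0
    if spec.bend_angle == 0:
        s0 = s1 = spec.bend_station
    w = np.clip((station - s0) / max(s1 - s0, 1e-9), 0.0, 1.0) if s1 > s0 else (
        1.0 if station >= s0 else 0.0)

    rp = spec.proximal_diameter / 2.0
    rd = spec.distal_diameter / 2.0
    c, s = np.cos(thetas), np.sin(thetas)
    sec = spec.proximal_section
    if sec is ProximalSection.CIRCULAR:
        prox = np.stack([rp * c, rp * s], axis=1)
    elif sec is ProximalSection.FLAT_LATERAL:
        cut = rp - spec.flat_depth
        if cut <= 0:
            raise GeometryError("flat_depth >= proximal radius")
        prox = np.stack([np.minimum(rp * c, cut), rp * s], axis=1)
    else:
        r = _trapezoid_radial(thetas, rp, spec.trapezoid_ap_depth)
        prox = np.stack([r * c, r * s], axis=1)
    dist = np.stack([rd * c, rd * s], axis=1)
    return (1.0 - w) * prox + w * dist


# -------------------------------------------------------------------- NailMesh
@dataclass
class NailMesh:
    """Triangulated nail surface in nail-local coordinates, with axis
    polyline and head-element axis."""

    spec: NailSpec
    surface: TriMesh
    axis: np.ndarray                 # (k, 3) polyline, proximal → distal
    axis_stations: np.ndarray        # (k,) arc-length stations
    head_axis_point: np.ndarray      # on the proximal axis segment
    head_axis_dir: np.ndarray        # unit
    arc_length_table: np.ndarray     # (n_vertices,) station per surface vertex
    bend_radius: float = DEFAULT_BEND_RADIUS

    @property
    def total_length(self) -> float:
        return self.spec.total_length


def build_nail_mesh(spec: NailSpec, circumferential_samples: int = 48,
                    axial_step: float = 2.0,
                    bend_radius: float = DEFAULT_BEND_RADIUS,
                    head_station: float = DEFAULT_HEAD_STATION) -> NailMesh:
    """Sweep the spec's cross-sections along its axis into a watertight mesh.

    Deterministic: identical spec + sampling yields a bit-identical vertex
    array.
    """
    if circumferential_samples < 12:
        raise InvalidSpecError("need >= 12 circumferential samples")
    if axial_step > 5.0 or axial_step <= 0:
        raise InvalidSpecError("axial_step must be in (0, 5] mm")
    n_rings = max(2, int(math.ceil(spec.total_length / axial_step)) + 1)
    stations = np.linspace(0.0, spec.total_length, n_rings)
    thetas = np.linspace(0.0, 2.0 * np.pi, circumferential_samples,
                         endpoint=False)
    pts, tan, lat = axis_path(spec, stations, bend_radius)
    ey = np.array([0.0, 1.0, 0.0])
    rings = np.empty((n_rings, circumferential_samples, 3))
    for i, st in enumerate(stations):
        xy = cross_section(spec, st, thetas, bend_radius)
        rings[i] = pts[i] + np.outer(xy[:, 0], lat[i]) + np.outer(xy[:, 1], ey)
    surface = mesh_from_rings(rings)
    # vertex order in mesh_from_rings: start-cap shrink rings, wall rings,
    # end-cap shrink rings, then the two cap centers
    n_shrink = max(1, circumferential_samples // 8)
    station_table = np.concatenate([
        np.zeros(n_shrink * circumferential_samples),
        np.repeat(stations, circumferential_samples),
        np.full(n_shrink * circumferential_samples, spec.total_length),
        [0.0, spec.total_length]])
    assert len(station_table) == surface.n_vertices
    hp, hd = head_axis(spec, min(head_station, 0.9 * spec.bend_station))
    return NailMesh(spec=spec, surface=surface, axis=pts,
                    axis_stations=stations, head_axis_point=hp,
                    head_axis_dir=hd, arc_length_table=station_table,
                    bend_radius=bend_radius)


def sample_surface(spec: NailSpec, density: float = 4.0,
                   bend_radius: float = DEFAULT_BEND_RADIUS):
    """Quasi-uniform samples of the nail's lateral (side) surface.

    ``density`` is the minimum sample density in samples/mm²; the flat tip
    faces are deliberately not sampled (impingement is a side-surface
    phenomenon and tip faces would dominate distance statistics).

    Returns ``(points (n, 3), stations (n,))`` in nail-local coordinates.
    """
    if density <= 0:
        raise InvalidSpecError("density must be positive")
    spacing = 1.0 / math.sqrt(density)
    n_rings = max(2, int(math.ceil(spec.total_length / spacing)) + 1)
    stations = np.linspace(0.0, spec.total_length, n_rings)
    perim = math.pi * spec.proximal_diameter
    n_circ = max(16, int(math.ceil(perim / spacing)))
    thetas = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    pts, tan, lat = axis_path(spec, stations, bend_radius)
    ey = np.array([0.0, 1.0, 0.0])
    out = np.empty((n_rings, n_circ, 3))
    for i, st in enumerate(stations):
        xy = cross_section(spec, st, thetas, bend_radius)
        out[i] = pts[i] + np.outer(xy[:, 0], lat[i]) + np.outer(xy[:, 1], ey)
    return out.reshape(-1, 3), np.repeat(stations, n_circ)
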