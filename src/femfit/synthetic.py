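"""Seeded generator of landmarked parametric endosteal femur models.

The study population this emulates is an East-Asian adult cohort, whose
femora typically show a shorter, more varus neck and a pronounced anterior
bow of the shaft. No morphometric data for the original 120 specimens exist,
so the shipped population defaults are literature-typical values, explicitly
labeled assumptions and fully overridable; see ``docs/methods.md``.

Geometry of one synthetic femur (endosteal canal model):

* the canal axis starts at the neck-base level (``trochanter_overhang`` mm
  below the GT apex), runs straight up to the apex plane, and distally
  follows a circular arc of radius ``anterior_bow_radius`` in the sagittal
  plane (∞ = straight shaft);
* the canal is a circular tube whose radius tapers linearly from
  ``proximal_flare_radius`` at the neck-base level to ``isthmus_radius`` at
  ``isthmus_station`` and stays constant below; flat caps close both ends;
* the GT apex sits on the proximal cap, offset laterally from the canal axis
  by a fixed fraction of the flare radius (the trochanter overhangs the
  canal laterally);
* the femoral head is a sphere of ``head_radius`` represented by its center
  landmark: head_center = neck_base + neck_length · n̂, where n̂ makes the
  neck-shaft angle with the fitted shaft axis and is rotated anteriorly by
  the anteversion angle. The head is not merged into the canal mesh — the
  placement and fitness stages use only the landmark and the canal surface.

Landmarks are exact by construction and every emitted model passes
:func:`femfit.femur.load_femur`-level integrity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigError, GeometryError
from .femur import FemurModel, Landmarks, fit_line_tls
from .mesh import mesh_from_rings

#: lateral offset of the GT apex from the canal axis, as a fraction of the
#: proximal flare radius (the greater trochanter overhangs the canal).
APEX_LATERAL_FRACTION = 0.45
#: anterior offset of the GT apex from the canal axis (same units): with an
#: anteriorly bowed shaft the trochanter tip lies anterior of the
#: distal-shaft chord, which also keeps the apex at the proximal extremity
#: of the mesh along the fitted shaft axis.
APEX_ANTERIOR_FRACTION = 0.35
#: posterior bias of the trochanteric (supra-neck-base) tube segment, as a
#: fraction of the flare radius. The greater trochanter is a posterolateral
#: structure: its anterior third overlies the canal corridor, which is what
#: makes the manufacturer's lateral-view entry rule anatomically sound. The
#: value r/3 places the anterior-third boundary of the trochanteric AP
#: extent exactly over the canal axis.
TROCHANTER_POSTERIOR_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class FemurParams:
    """Shape parameters of one synthetic femur (mm / degrees)."""

    femur_length: float
    isthmus_radius: float
    isthmus_station: float
    proximal_flare_radius: float
    anterior_bow_radius: float      # np.inf = straight shaft
    neck_shaft_angle: float
    neck_length: float
    anteversion: float
    head_radius: float
    trochanter_overhang: float

    def __post_init__(self):
        for name in ("femur_length", "isthmus_radius", "isthmus_station",
                     "proximal_flare_radius", "neck_length", "head_radius",
                     "trochanter_overhang"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.proximal_flare_radius < self.isthmus_radius:
            raise ConfigError("proximal_flare_radius must be >= isthmus_radius")
        if not (90 < self.neck_shaft_angle < 160):
            raise ConfigError("neck_shaft_angle out of (90, 160) degrees")
        if not (self.anterior_bow_radius > 200):
            raise ConfigError("anterior_bow_radius must exceed 200 mm (or be inf)")
        if self.trochanter_overhang >= self.isthmus_station:
            raise ConfigError("trochanter_overhang must be proximal of the isthmus")

    def scaled(self, k: float) -> "FemurParams":
        d = asdict(self)
        for name in ("femur_length", "isthmus_radius", "isthmus_station",
                     "proximal_flare_radius", "neck_length", "head_radius",
                     "trochanter_overhang"):
            d[name] *= k
        if math.isfinite(self.anterior_bow_radius):
            d["anterior_bow_radius"] *= k
        return FemurParams(**d)


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal marginal for one parameter."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")
        if not (self.lo < self.hi):
            raise ConfigError(f"infeasible bounds: [{self.lo}, {self.hi})")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                             random_state=rng)


def _d(mean, sd, lo=None, hi=None):
    return ParamDist(mean, sd,
                     mean - 3 * sd if lo is None else lo,
                     mean + 3 * sd if hi is None else hi)


#: literature-typical East-Asian adult defaults (documented assumptions)
DEFAULT_POPULATION: dict[str, ParamDist] = {
    "femur_length": _d(430.0, 20.0),
    "isthmus_radius": _d(5.5, 0.8, lo=3.5),
    "isthmus_station": _d(180.0, 15.0),
    "proximal_flare_radius": _d(14.0, 1.5, lo=10.0),
    "anterior_bow_radius": _d(900.0, 150.0, lo=500.0),
    "neck_shaft_angle": _d(129.0, 5.0),
    "neck_length": _d(52.0, 5.0),
    "anteversion": _d(15.0, 5.0),
    "head_radius": _d(22.0, 1.5),
    "trochanter_overhang": _d(42.0, 4.0, lo=25.0),
}

_PARAM_ORDER = tuple(DEFAULT_POPULATION)  # fixed draw order for determinism


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling plan for a synthetic cohort."""

    n: int
    seed: int
    distributions: dict = None  # per-parameter overrides of DEFAULT_POPULATION

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("population size n must be >= 1")
        dists = dict(DEFAULT_POPULATION)
        for key, val in (self.distributions or {}).items():
            if key not in dists:
                raise ConfigError(f"unknown population parameter {key!r}")
            dists[key] = val if isinstance(val, ParamDist) else ParamDist(**val)
        object.__setattr__(self, "distributions", dists)


def sample_population(spec: PopulationSpec) -> list[FemurParams]:
    """Draw ``spec.n`` parameter sets, fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cols = {name: spec.distributions[name].sample(spec.n, rng)
            for name in _PARAM_ORDER}
    out = []
    for i in range(spec.n):
        kw = {name: float(cols[name][i]) for name in _PARAM_ORDER}
        # clip pathological joint draws rather than rejecting (keeps count at n)
        kw["isthmus_radius"] = min(kw["isthmus_radius"],
                                   kw["proximal_flare_radius"])
        kw["trochanter_overhang"] = min(kw["trochanter_overhang"],
                                        0.5 * kw["isthmus_station"])
        out.append(FemurParams(**kw))
    return out


# ----------------------------------------------------------------- geometry
def canal_axis(params: FemurParams, stations,
               apex_lateral_fraction: float = APEX_LATERAL_FRACTION,
               apex_anterior_fraction: float = APEX_ANTERIOR_FRACTION
               ) -> np.ndarray:
    """Canal-axis points at arc-length ``stations`` measured from the apex
    plane (world coordinates of the generated model; the GT apex is at the
    origin, offset laterally/anteriorly from the canal axis)."""
    s = np.atleast_1d(np.asarray(stations, dtype=float))
    a_off = apex_lateral_fraction * params.proximal_flare_radius
    b_off = apex_anterior_fraction * params.proximal_flare_radius
    h = params.trochanter_overhang
    out = np.empty(s.shape + (3,))
    out[:, 0] = -a_off
    prox = s <= h
    out[prox, 1] = -b_off
    out[prox, 2] = s[prox]
    if (~prox).any():
        R = params.anterior_bow_radius
        if math.isfinite(R):
            u = (s[~prox] - h) / R
            out[~prox, 1] = -b_off - R * (1.0 - np.cos(u))
            out[~prox, 2] = h + R * np.sin(u)
        else:
            out[~prox, 1] = -b_off
            out[~prox, 2] = s[~prox]
    return out


def canal_radius(params: FemurParams, stations) -> np.ndarray:
    s = np.atleast_1d(np.asarray(stations, dtype=float))
    h, ist = params.trochanter_overhang, params.isthmus_station
    w = np.clip((s - h) / (ist - h), 0.0, 1.0)
    return ((1.0 - w) * params.proximal_flare_radius
            + w * params.isthmus_radius)


def _axis_tangent(params: FemurParams, stations) -> np.ndarray:
    s = np.atleast_1d(np.asarray(stations, dtype=float))
    out = np.zeros(s.shape + (3,))
    h = params.trochanter_overhang
    prox = s <= h
    out[prox] = [0.0, 0.0, 1.0]
    R = params.anterior_bow_radius
    if math.isfinite(R):
        u = (s[~prox] - h) / R
        out[~prox, 1] = -np.sin(u)
        out[~prox, 2] = np.cos(u)
    else:
        out[~prox] = [0.0, 0.0, 1.0]
    return out


def build_femur(params: FemurParams, femur_id: str = "synthetic",
                n_circ: int = 40, axial_step: float = 2.5,
                apex_lateral_fraction: float = APEX_LATERAL_FRACTION,
                apex_anterior_fraction: float = APEX_ANTERIOR_FRACTION,
                trochanter_posterior_fraction: float =
                TROCHANTER_POSTERIOR_FRACTION) -> FemurModel:
    """Realize a parameter set as a watertight endosteal model with exact
    landmarks. Deterministic."""
    L = params.femur_length
    R = params.anterior_bow_radius
    if math.isfinite(R) and R < L / math.pi:
        raise GeometryError(
            f"anterior_bow_radius {R:.0f} mm self-intersects a femur of "
            f"length {L:.0f} mm")
    n_rings = max(3, int(math.ceil(L / axial_step)) + 1)
    stations = np.linspace(0.0, L, n_rings)
    centers = canal_axis(params, stations, apex_lateral_fraction,
                        apex_anterior_fraction)
    # trochanteric segment biased posteriorly (GT is posterolateral); the
    # ring centers rejoin the canal axis smoothly at the neck-base level
    h = params.trochanter_overhang
    delta = trochanter_posterior_fraction * params.proximal_flare_radius
    ramp = np.clip(1.0 - stations / h, 0.0, 1.0) ** 2
    centers = centers.copy()
    centers[:, 1] -= delta * ramp
    tangents = _axis_tangent(params, stations)
    radii = canal_radius(params, stations)
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.cross(tangents, ex)
    ey /= np.linalg.norm(ey, axis=1, keepdims=True)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    rings = (centers[:, None, :]
             + radii[:, None, None] * (cos_t[None, :, None] * ex[None, None, :]
                                       + sin_t[None, :, None] * ey[:, None, :]))
    mesh = mesh_from_rings(rings)

    # landmarks (exact by construction)
    shaft_s = np.linspace(0.25 * L, 0.75 * L, 7)
    shaft_pts = canal_axis(params, shaft_s, apex_lateral_fraction,
                           apex_anterior_fraction)
    centroid, z_fit = fit_line_tls(shaft_pts)
    if z_fit[2] < 0:
        z_fit = -z_fit
    y_fit = np.array([0.0, 1.0, 0.0])
    y_fit = y_fit - (y_fit @ z_fit) * z_fit
    y_fit /= np.linalg.norm(y_fit)
    x_fit = np.cross(y_fit, z_fit)
    nsa = math.radians(params.neck_shaft_angle)
    av = math.radians(params.anteversion)
    n_hat = (math.cos(nsa) * z_fit
             + math.sin(nsa) * (math.cos(av) * (-x_fit) + math.sin(av) * y_fit))
    neck_base = canal_axis(params, params.trochanter_overhang,
                           apex_lateral_fraction, apex_anterior_fraction)[0]
    head_center = neck_base + params.neck_length * n_hat
    landmarks = Landmarks(gt_apex=np.zeros(3), head_center=head_center,
                          shaft_axis_points=shaft_pts,
                          anterior_dir=np.array([0.0, 1.0, 0.0]), side="R",
                          neck_base=neck_base)
    return FemurModel(mesh, landmarks, femur_id)


def cylinder_canal(radius: float, length: float, femur_id: str = "cylinder",
                   n_circ: int = 48, axial_step: float = 2.0) -> FemurModel:
    """Synthetic straight cylindrical canal with the apex at the cap center.

    Analytic scaffold for closed-form penetration oracles: the canal axis is
    the z-axis, the apex plane is z = 0 and the canal extends to z = length.
    """
    params = FemurParams(femur_length=length, isthmus_radius=radius,
                         isthmus_station=length / 2,
                         proximal_flare_radius=radius,
                         anterior_bow_radius=np.inf, neck_shaft_angle=130.0,
                         neck_length=max(50.0, 3 * radius), anteversion=0.0,
                         head_radius=max(20.0, 2 * radius),
                         trochanter_overhang=length / 4)
    return build_femur(params, femur_id, n_circ=n_circ, axial_step=axial_step,
                       apex_lateral_fraction=0.0, apex_anterior_fraction=0.0,
                       trochanter_posterior_fraction=0.0)


# ------------------------------------------------------- parameter recovery
def estimate_bow_radius(model: FemurModel, z_lo_frac: float = 0.16,
                        z_hi_frac: float = 0.98, bin_width: float = 16.0
                        ) -> float:
    """Re-estimate the sagittal bow radius from the emitted mesh alone.

    Bins mesh vertices along the frame z-axis (distal of the straight
    trochanteric segment), takes per-bin centroids (ring centers lie on the
    canal axis) and fits a circle to their sagittal (y, z) coordinates:
    Kåsa algebraic fit refined by geometric least squares.
    """
    from scipy.optimize import least_squares

    c = model.frame.to_frame(model.endosteal_mesh.vertices)
    z = c[:, 2]
    z0, z1 = z.min() + z_lo_frac * np.ptp(z), z.min() + z_hi_frac * np.ptp(z)
    edges = np.arange(z0, z1, bin_width)
    ys, zs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (z >= lo) & (z < hi)
        if m.sum() >= 10:
            ys.append(c[m, 1].mean())
            zs.append(c[m, 2].mean())
    y, zz = np.asarray(ys), np.asarray(zs)
    if len(y) < 3:
        raise GeometryError("too few axis samples for a circle fit")
    A = np.stack([y, zz, np.ones_like(y)], axis=1)
    b = y ** 2 + zz ** 2
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    cy, cz = coef[0] / 2, coef[1] / 2
    r0 = math.sqrt(max(coef[2] + cy ** 2 + cz ** 2, 1e-6))

    def resid(p):
        return np.hypot(y - p[0], zz - p[1]) - p[2]

    sol = least_squares(resid, x0=[cy, cz, r0], method="lm")
    return float(abs(sol.x[2]))


def estimate_isthmus_radius(model: FemurModel, bin_width: float = 6.0) -> float:
    """Minimum canal radius, from per-bin mean distance of mesh vertices to
    the locally fitted axis (tangent from neighboring bin centroids)."""
    c = model.frame.to_frame(model.endosteal_mesh.vertices)
    z = c[:, 2]
    edges = np.arange(z.min() + 5.0, z.max() - 5.0, bin_width)
    cents, members = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (z >= lo) & (z < hi)
        if m.sum() >= 10:
            cents.append(c[m].mean(axis=0))
            members.append(c[m])
    cents = np.asarray(cents)
    radii = []
    for i in range(1, len(cents) - 1):
        t = cents[i + 1] - cents[i - 1]
        t = t / np.linalg.norm(t)
        d = members[i] - cents[i]
        perp = d - np.outer(d @ t, t)
        radii.append(np.linalg.norm(perp, axis=1).mean())
    if not radii:
        raise GeometryError("too few bins for a radius estimate")
    return float(min(radii))


def estimate_neck_shaft_angle(model: FemurModel) -> float:
    """Angle (degrees) between the neck axis (head_center − neck_base) and
    the distal-pointing shaft axis."""
    lm = model.landmarks
    if lm.neck_base is None:
        raise GeometryError("neck_base landmark required to estimate the "
                            "neck-shaft angle")
    n = lm.head_center - lm.neck_base
    n = n / np.linalg.norm(n)
    return float(math.degrees(math.acos(np.clip(n @ model.frame.z_axis, -1, 1))))


def sagittal_sagitta(model: FemurModel) -> float:
    """Maximum sagittal deviation of per-bin axis centroids from the chord
    between the proximal-most and distal-most centroid (bow severity)."""
    c = model.frame.to_frame(model.endosteal_mesh.vertices)
    z = c[:, 2]
    edges = np.arange(z.min() + 5.0, z.max() - 5.0, 8.0)
    cents = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (z >= lo) & (z < hi)
        if m.sum() >= 10:
            cents.append([c[m, 1].mean(), c[m, 2].mean()])
    cents = np.asarray(cents)
    p0, p1 = cents[0], cents[-1]
    d = (p1 - p0) / np.linalg.norm(p1 - p0)
    rel = cents - p0
    return float(np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]).max())
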