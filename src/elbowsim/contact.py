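"""Deformable articular contact between discretized cartilage elements.

Each humeral cartilage element is a point-area sample rigidly attached to
the humerus.  Against each opposing cartilage surface (the ulnar sigmoid
notch, the radial head dish) it develops a normal force from the modified
Hertzian law

    Fc = kc * delta**n + Bc(delta) * delta_dot        (delta > 0)

with the damping coefficient ramped in by a cubic smoothstep so that the
force is continuous at first touch:

    Bc(delta) = Bmax * s**2 * (3 - 2 s),   s = delta / dmax,  clamped to [0, 1].

Contact stiffness can either be taken from the configured defaults
(126 N/mm ulnohumeral, 105 N/mm radiohumeral for a 25 mm² element) or
re-derived from cartilage material properties through the elastic
foundation (bed-of-springs) model, where the pressure over a thin layer of
thickness ``h`` is

    p = (1 - nu) E / ((1 + nu)(1 - 2 nu) h) * d

and the per-element stiffness is ``p/d`` times the element area.  Note the
two routes do not coincide for the default material values; both are
exposed and neither is silently preferred.

Analytic opposing-surface patches (:class:`NotchSurface`,
:class:`DishSurface`, :class:`PlaneSurface`) provide smooth, vectorised
penetration queries for the quasistatic solver; :func:`element_penetration`
answers the same query against an arbitrary oriented triangle mesh for
user-supplied geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    ContactElement,
    GeometryConfig,
    _flange_slope,
    groove_drift_rate,
    trochlea_profile,
    trochlea_profile_slope,
)

__all__ = [
    "ContactParameters",
    "ElasticFoundationInputs",
    "ContactState",
    "damping_coefficient",
    "contact_normal_force",
    "foundation_stiffness",
    "element_penetration",
    "contact_map",
    "NotchSurface",
    "DishSurface",
    "PlaneSurface",
]


# --------------------------------------------------------------------------
# parameters & state
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactParameters:
    """Constants of the modified Hertzian contact law.

    ``kc`` is the per-element contact stiffness in N/mm (defaults assume a
    5 x 5 mm element), ``n`` the nonlinear power exponent, ``Bmax`` the
    saturated damping in Ns/mm and ``dmax`` the penetration at which the
    damping saturates.
    """

    kc: float = 126.0
    n: float = 1.0
    Bmax: float = 2.0
    dmax: float = 0.1

    def validate(self) -> None:
        if not self.kc > 0:
            raise ValueError(f"ContactParameters.kc must be > 0, got {self.kc!r}")
        if not self.n >= 1:
            raise ValueError(f"ContactParameters.n must be >= 1, got {self.n!r}")
        if self.Bmax < 0:
            raise ValueError(f"ContactParameters.Bmax must be >= 0, got {self.Bmax!r}")
        if not self.dmax > 0:
            raise ValueError(f"ContactParameters.dmax must be > 0, got {self.dmax!r}")


#: defaults adopted for the two articulations (per 25 mm² element)
ULNOHUMERAL = ContactParameters(kc=126.0)
RADIOHUMERAL = ContactParameters(kc=105.0)


@dataclass(frozen=True)
class ElasticFoundationInputs:
    """Inputs of the elastic-foundation stiffness estimate."""

    E: float            # Young's modulus, MPa
    nu: float           # Poisson's ratio
    h: float            # combined cartilage thickness, mm
    element_area: float = 25.0   # mm^2

    def validate(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be > 0, got {self.E!r}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(
                f"nu must lie in [0, 0.5); the incompressible limit nu >= 0.5 "
                f"is singular, got {self.nu!r}"
            )
        if not self.h > 0:
            raise ValueError(f"h must be > 0, got {self.h!r}")
        if not self.element_area > 0:
            raise ValueError(f"element_area must be > 0, got {self.element_area!r}")


@dataclass
class ContactState:
    """Instantaneous state of one element-surface pair."""

    delta: float        # penetration, mm (negative = separated)
    delta_dot: float    # penetration rate, mm/s (positive = approaching)
    Fc: float           # normal force, N
    p: float            # pressure, MPa


# --------------------------------------------------------------------------
# constitutive closed forms
# --------------------------------------------------------------------------

def damping_coefficient(delta, params: ContactParameters):
    """Penetration-dependent damping Bc(delta), Ns/mm.

    Zero for separation, ``Bmax`` beyond ``dmax``, cubic smoothstep in
    between; C1-continuous at both boundaries.  Accepts scalars or arrays.
    """
    delta = np.asarray(delta, dtype=float)
    s = np.clip(delta / params.dmax, 0.0, 1.0)
    out = params.Bmax * s * s * (3.0 - 2.0 * s)
    return out.item() if out.ndim == 0 else out


def contact_normal_force(delta, delta_dot, params: ContactParameters):
    """Normal contact force of the modified Hertzian law, N.

    Returns 0 for separation and clamps the total at zero from below — the
    damper may reduce but never reverse the compressive force (no
    adhesion).  Accepts scalars or arrays.
    """
    delta = np.asarray(delta, dtype=float)
    delta_dot = np.asarray(delta_dot, dtype=float)
    elastic = params.kc * np.where(delta > 0.0, delta, 0.0) ** params.n
    f = elastic + damping_coefficient(delta, params) * delta_dot
    out = np.where(delta > 0.0, np.maximum(f, 0.0), 0.0)
    return out.item() if out.ndim == 0 else out


def foundation_stiffness(inputs: ElasticFoundationInputs) -> float:
    """Per-element contact stiffness from the elastic foundation model, N/mm.

    ``(1 - nu) E / ((1 + nu)(1 - 2 nu) h)`` is the layer modulus (pressure
    per unit deformation); multiplying by the element area gives the
    stiffness of one discretized cartilage element.
    """
    inputs.validate()
    modulus = (1.0 - inputs.nu) * inputs.E / (
        (1.0 + inputs.nu) * (1.0 - 2.0 * inputs.nu) * inputs.h
    )
    return modulus * inputs.element_area


# --------------------------------------------------------------------------
# analytic opposing-surface patches
# --------------------------------------------------------------------------
#
# Each patch lives in the local frame of the body that owns it and maps
# local query points to (delta, grad) where delta > 0 means the point has
# interpenetrated the cartilage and grad = d delta / d point is the
# (near-unit) contact direction pointing *into* the owning body's material.
# Smoothness of delta in the point is what the quasistatic minimiser needs.


class PlaneSurface:
    """Half-space ``(p - point) . normal < 0`` is material."""

    def __init__(self, point, normal):
        self.point = np.asarray(point, dtype=float)
        n = np.asarray(normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def penetration(self, pts: np.ndarray):
        pts = np.atleast_2d(pts)
        delta = -(pts - self.point) @ self.normal
        grad = np.broadcast_to(-self.normal, pts.shape).copy()
        return delta, grad


class NotchSurface:
    """Greater sigmoid notch: concave grooved spool in the ulna frame.

    The notch is the surface of revolution about the ulnar x-axis with
    radius profile equal to the trochlear profile plus the articular
    clearance; material lies radially *outside* the profile, over an
    angular sector of ``wrap_angle`` centred opposite the cup opening
    (the opening faces anterior-proximal, toward the humeral shaft).
    Beyond the sector the surface flares open quadratically — the
    olecranon and coronoid margins of a real notch curl away from the
    trochlea — which keeps the penetration field C1 when a loaded element
    slides across a margin.  Axially the parabolic groove profile simply
    continues past the lips, flaring the same way.
    """

    #: flare curvature past the sector margins, mm per rad^2; steep enough
    #: that no equilibrium exists with the trochlea fully outside the notch
    FLARE = 300.0

    def __init__(self, cfg: GeometryConfig):
        self.cfg = cfg
        self.clearance = cfg.notch_clearance
        self.half_wrap = math.radians(cfg.sigmoid_notch_wrap_angle / 2.0)
        b = math.radians(45.0)
        self.bisector = -np.array([math.sin(b), math.cos(b)])   # (y, z), cup bottom

    def penetration(self, pts: np.ndarray):
        pts = np.atleast_2d(pts)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        rho = np.hypot(y, z)
        valid = rho > 1e-9
        rho_safe = np.where(valid, rho, 1.0)

        by, bz = self.bisector
        dot = y * by + z * bz
        cross = by * z - bz * y
        ang = np.arctan2(cross, dot)

        # the notch ridge runs with the same oblique course as the
        # trochlear groove (congruent helix): the profile shift follows the
        # angle from the cup bottom exactly as the groove shifts with patch
        # angle, so the nested reference pose mates with uniform clearance
        rn = trochlea_profile(x, self.cfg, ang) + self.clearance
        over = np.maximum(0.0, np.abs(ang) - self.half_wrap)
        delta = np.where(valid, rho - rn - self.FLARE * over**2, -1e6)

        rp = trochlea_profile_slope(x, self.cfg, ang)
        # only the groove dip drifts with the angle; the medial flange is
        # fixed in x and does not contribute to the angular coupling
        rp_groove = rp - _flange_slope(x)
        m = groove_drift_rate(ang, self.cfg)
        # d ang / d (y, z) = (dot * grad(cross) - cross * grad(dot)) / rho^2
        dang_y = (dot * (-bz) - cross * by) / rho_safe**2
        dang_z = (dot * by - cross * bz) / rho_safe**2
        # dependence on ang: ridge shift (+m * rp_groove) and the rim flare
        fl = m * rp_groove - 2.0 * self.FLARE * over * np.sign(ang)
        grad = np.stack([
            -rp,
            y / rho_safe + fl * dang_y,
            z / rho_safe + fl * dang_z,
        ], axis=1)
        return delta, grad


class DishSurface:
    """Radial head dish: shallow concave spherical cap in the radius frame.

    The centre of curvature sits on the +z (proximal) axis at the dish
    radius, so the surface passes through the body origin; material lies
    beyond the dish radius from the centre, inside the cap cone.
    """

    #: rim flare curvature, mm per rad^2
    FLARE = 40.0

    def __init__(self, cfg: GeometryConfig):
        self.R = cfg.capitellum_radius + cfg.notch_clearance
        self.center = np.array([0.0, 0.0, self.R])
        self.cap = math.radians(cfg.radial_dish_cap_angle)

    def penetration(self, pts: np.ndarray):
        pts = np.atleast_2d(pts)
        v = pts - self.center
        d = np.linalg.norm(v, axis=1)
        valid = d > 1e-9
        d_safe = np.where(valid, d, 1.0)
        # polar angle from the dish axis (-z from the centre of curvature);
        # past the cap rim the dish flares away quadratically, C1 at the rim
        cosang = np.clip(-v[:, 2] / d_safe, -1.0, 1.0)
        ang = np.arccos(cosang)
        over = np.maximum(0.0, ang - self.cap)
        delta = np.where(valid, d - self.R - self.FLARE * over**2, -1e6)

        grad = v / d_safe[:, None]
        # d ang / d v  (perpendicular to v), guarded at the axis pole
        sin_ang = np.sqrt(np.maximum(1e-12, 1.0 - cosang**2))
        dang = np.empty_like(v)
        dang[:, 0] = cosang * v[:, 0] / (d_safe**2 * sin_ang)
        dang[:, 1] = cosang * v[:, 1] / (d_safe**2 * sin_ang)
        dang[:, 2] = sin_ang / d_safe
        grad = grad - (2.0 * self.FLARE * over)[:, None] * dang
        return delta, grad


# --------------------------------------------------------------------------
# mesh-based penetration query
# --------------------------------------------------------------------------

def nearest_on_mesh(mesh, point):
    """Nearest surface point by exhaustive per-triangle projection.

    Returns ``(closest_point, distance, face_index)``.  Linear in the face
    count but fully vectorised; fine for the mesh sizes this package
    queries point-by-point.
    """
    from trimesh.triangles import closest_point as _tri_closest

    point = np.asarray(point, dtype=float)
    ok = np.flatnonzero(mesh.area_faces > 1e-12)   # skip degenerate faces
    tris = mesh.triangles[ok]
    candidates = _tri_closest(tris, np.broadcast_to(point, (len(tris), 3)))
    d2 = np.einsum("ij,ij->i", candidates - point, candidates - point)
    best = int(np.argmin(d2))
    return candidates[best], float(np.sqrt(d2[best])), int(ok[best])


def winding_number(mesh, point) -> float:
    """Generalized winding number of a closed mesh about a point.

    Sum of signed solid angles over the faces divided by 4 pi: ~1 inside,
    ~0 outside (van Oosterom-Strackee).  Exact inside/outside test for
    watertight meshes without spatial-index dependencies.
    """
    point = np.asarray(point, dtype=float)
    t = mesh.triangles - point
    a, b, c = t[:, 0], t[:, 1], t[:, 2]
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    lc = np.linalg.norm(c, axis=1)
    det = np.einsum("ij,ij->i", a, np.cross(b, c))
    denom = (
        la * lb * lc
        + np.einsum("ij,ij->i", a, b) * lc
        + np.einsum("ij,ij->i", b, c) * la
        + np.einsum("ij,ij->i", c, a) * lb
    )
    omega = 2.0 * np.arctan2(det, denom)
    return float(np.sum(omega) / (4.0 * math.pi))


def element_penetration(element: ContactElement, opposing_surface,
                        element_velocity=None, surface_velocity=None):
    """Signed penetration of an element centre into an oriented mesh.

    ``delta`` is positive when the centre lies inside the opposing
    cartilage material.  If the rigid-body point velocities of the contact
    pair are supplied, the penetration rate ``delta_dot`` (positive when
    approaching) is returned as well, otherwise 0.

    The mesh must have a consistent outward orientation; watertight meshes
    use the exact inside/outside test, open oriented sheets use the
    nearest-face normal.
    """
    mesh = opposing_surface
    point = np.asarray(element.center, dtype=float)

    closest, dist, tri = nearest_on_mesh(mesh, point)
    normal = mesh.face_normals[tri]
    if mesh.is_watertight:
        inside = winding_number(mesh, point) > 0.5
        delta = float(dist if inside else -dist)
    elif mesh.is_winding_consistent:
        outside = (point - closest) @ normal
        delta = float(-math.copysign(dist, outside) if dist > 0 else 0.0)
    else:
        raise ValueError("opposing surface has no consistent outward orientation")

    delta_dot = 0.0
    if element_velocity is not None or surface_velocity is not None:
        ve = np.zeros(3) if element_velocity is None else np.asarray(element_velocity, float)
        vs = np.zeros(3) if surface_velocity is None else np.asarray(surface_velocity, float)
        # approaching means the element moves against the outward surface normal
        delta_dot = float(-(ve - vs) @ normal)
    return delta, delta_dot


# --------------------------------------------------------------------------
# pressure maps
# --------------------------------------------------------------------------

@dataclass
class ContactMapSummary:
    peak_pressure: float        # MPa
    contact_area: float         # mm^2 (count of loaded elements x element area)
    n_active: int


def contact_map(states: list[tuple[ContactElement, ContactState]]):
    """Per-element pressure on the unrolled 2-D map plus a scalar summary.

    Returns ``(table, summary)`` where ``table`` is a record array with
    columns ``(id, u, v, region, delta, Fc, p)`` and the summary holds the
    peak pressure and the loaded contact area.
    """
    import pandas as pd

    rows = []
    for element, state in states:
        rows.append(
            dict(
                id=element.id,
                u=element.map_uv[0],
                v=element.map_uv[1],
                region=element.region,
                area=element.area,
                delta=state.delta,
                Fc=state.Fc,
                p=state.Fc / element.area,
            )
        )
    table = pd.DataFrame(rows)
    if len(table):
        active = table["delta"] > 0.0
        summary = ContactMapSummary(
            peak_pressure=float(table["p"].max()) if len(table) else 0.0,
            contact_area=float(table.loc[active, "area"].sum()),
            n_active=int(active.sum()),
        )
    else:
        summary = ContactMapSummary(0.0, 0.0, 0)
    return table, summary
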