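"""Seeded parametric elbow geometry.

Generates a complete right-arm elbow — distal humerus (grooved trochlea +
capitellum), proximal ulna (greater sigmoid notch), radial head dish, a
discretized humeral cartilage element set, a collateral-ligament attachment
atlas and anatomical landmarks — as a deterministic function of a
:class:`GeometryConfig` and its seed.  The generator stands in for
subject-specific CT/MRI surface reconstructions: it preserves the articular
congruence (groove/ridge engagement of the ulnohumeral joint, nested
radiocapitellar sphere/dish) and the medial/lateral constraint structure
that make the medial collateral ligament the dominant medial stabiliser,
without claiming subject-specific shape fidelity.

Conventions
-----------
Units are millimetres / Newtons / seconds / MPa.  All frames are
right-handed; the arm is a *right* arm.  In every body frame:

* ``+x`` — lateral, along the flexion (trans-epicondylar) axis,
* ``+y`` — anterior,
* ``+z`` — proximal (long axis, pointing toward the shoulder).

The humerus body frame has its origin at the trochlea (flexion-axis)
centre; the ulna body frame origin coincides with it at the nested
reference pose, and the radius body frame origin sits at the radial head
centre.  Medial structures therefore live at negative ``x``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

__all__ = [
    "GeometryConfig",
    "ContactElement",
    "Attachment",
    "WrapPrimitive",
    "ElbowGeometry",
    "generate_elbow",
    "discretize_cartilage",
    "save_geometry",
    "load_atlas",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the synthetic elbow.

    Lengths in mm, angles in degrees.  The defaults describe an
    average-sized adult right elbow scaled so that the standard 345 mm
    vertical humeral-head stroke sweeps flexion from the 45 degree starting
    pose to roughly 135 degrees.
    """

    trochlea_radius: float = 12.0          # radius at the trochlear lips
    trochlea_groove_depth: float = 2.2     # lip radius minus groove-floor radius
    trochlea_width: float = 20.0           # medial-lateral extent of the spool
    capitellum_radius: float = 10.0
    capitellum_offset: float = 16.0        # x of the capitellum centre (on the flexion axis)
    sigmoid_notch_wrap_angle: float = 185.0  # angular coverage of the ulnar notch
    trochlea_groove_obliquity: float = 12.0   # lateral drift of the groove centre, mm/rad
    notch_clearance: float = 0.05          # radial articular clearance of the notch
    radial_head_radius: float = 9.0        # physical head cylinder (annular wrap surface)
    radial_dish_cap_angle: float = 70.0    # half-angle of the shallow radial-head dish
    cartilage_thickness_uh: float = 4.0    # combined ulnohumeral cartilage (h in Eq. of state)
    cartilage_thickness_rh: float = 4.8    # combined radiohumeral cartilage
    element_edge: float = 5.0              # cartilage discretization edge
    humerus_length: float = 300.0
    ulna_length: float = 232.0             # trochlear notch centre to ulnar styloid
    radius_length: float = 232.0
    initial_flexion: float = 45.0          # degrees, reference (generation) pose
    seed: int = 1

    def validate(self) -> None:
        positive = (
            "trochlea_radius", "trochlea_groove_depth", "trochlea_width",
            "capitellum_radius", "capitellum_offset", "radial_head_radius",
            "radial_dish_cap_angle", "cartilage_thickness_uh",
            "cartilage_thickness_rh", "element_edge", "humerus_length",
            "ulna_length", "radius_length",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"GeometryConfig.{name} must be > 0, got {getattr(self, name)!r}")
        if not (90.0 < self.sigmoid_notch_wrap_angle < 200.0):
            raise ValueError(
                "GeometryConfig.sigmoid_notch_wrap_angle must lie in (90, 200) degrees, "
                f"got {self.sigmoid_notch_wrap_angle!r}"
            )
        if self.trochlea_groove_depth >= self.trochlea_radius:
            raise ValueError("GeometryConfig.trochlea_groove_depth must be smaller than trochlea_radius")
        if self.notch_clearance < 0:
            raise ValueError("GeometryConfig.notch_clearance must be >= 0")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ContactElement:
    """One discretized humeral cartilage element.

    ``center`` and ``normal`` are expressed in the humerus body frame;
    ``map_uv`` is the unrolled 2-D coordinate used for pressure-map
    rendering; ``region`` is ``"trochlea"`` or ``"capitellum"``.
    """

    id: int
    center: np.ndarray
    normal: np.ndarray
    area: float
    map_uv: tuple[float, float]
    region: str


@dataclass(frozen=True)
class WrapPrimitive:
    """Convex wrapping obstacle fixed to a body.

    ``kind`` is ``"sphere"`` (``point`` = centre) or ``"cylinder"``
    (``point`` = a point on the axis, ``axis`` = unit direction).
    """

    kind: str
    body: str
    point: tuple[float, float, float]
    radius: float
    axis: tuple[float, float, float] | None = None


@dataclass
class Attachment:
    """Ligament bundle endpoints, body-anchored, plus wrap obstacles."""

    complex: str                     # MCL_AB | MCL_PB | LUCL | RCL | annular
    origin_body: str
    origin: np.ndarray               # local coords of origin_body
    insertion_body: str
    insertion: np.ndarray
    wraps: tuple[WrapPrimitive, ...] = ()


@dataclass
class ElbowGeometry:
    """Complete synthetic elbow: meshes, elements, atlas, landmarks."""

    config: GeometryConfig
    bone_meshes: dict[str, trimesh.Trimesh]
    cartilage_meshes: dict[str, trimesh.Trimesh]
    contact_elements: list[ContactElement]
    attachments: dict[str, Attachment]
    landmarks: dict[str, dict[str, np.ndarray]]   # body -> name -> local point

    @property
    def n_bundles(self) -> int:
        return len(self.attachments)

    def elements_in(self, region: str) -> list[ContactElement]:
        return [e for e in self.contact_elements if e.region == region]


# --------------------------------------------------------------------------
# parametric articular surfaces (analytic helpers shared with the contact
# module; kept here because they define the geometry)
# --------------------------------------------------------------------------

#: patch angle (rad) over which the oblique groove course saturates; the
#: obliquity of the articular groove is concentrated in the mid arc
_DRIFT_SATURATION = 0.95

#: flanges of the trochlear spool: the prominent medial flange and the
#: smaller lateral (capitulotrochlear) ridge.  Each is a C1 quadratic
#: radius rise beyond its onset; (rise mm, onset mm, width mm)
_FLANGE_MEDIAL = (0.0, 4.0, 4.0)
_FLANGE_LATERAL = (3.0, 8.0, 4.0)


def groove_drift(phi, cfg: GeometryConfig):
    """Lateral offset of the groove centre at patch angle ``phi`` (mm)."""
    phi = np.asarray(phi, dtype=float)
    return cfg.trochlea_groove_obliquity * _DRIFT_SATURATION * np.tanh(
        phi / _DRIFT_SATURATION
    )


def groove_drift_rate(phi, cfg: GeometryConfig):
    """d(groove_drift)/d(phi), mm per radian."""
    phi = np.asarray(phi, dtype=float)
    t = np.tanh(phi / _DRIFT_SATURATION)
    return cfg.trochlea_groove_obliquity * (1.0 - t * t)


def _flange(x):
    """Flange rise of the spool radius (mm): C1, zero in the groove span."""
    x = np.asarray(x, dtype=float)
    rm, om, wm = _FLANGE_MEDIAL
    rl, ol, wl = _FLANGE_LATERAL
    tm = np.maximum(0.0, (-x - om) / wm)
    tl = np.maximum(0.0, (x - ol) / wl)
    return rm * tm * tm + rl * tl * tl


def _flange_slope(x):
    x = np.asarray(x, dtype=float)
    rm, om, wm = _FLANGE_MEDIAL
    rl, ol, wl = _FLANGE_LATERAL
    tm = np.maximum(0.0, (-x - om) / wm)
    tl = np.maximum(0.0, (x - ol) / wl)
    return -2.0 * rm * tm / wm + 2.0 * rl * tl / wl


def trochlea_profile(x, cfg: GeometryConfig, phi=0.0):
    """Trochlear spool radius r(x, phi): C1 raised-cosine groove, oblique course.

    The articular spool is a cylinder at the lip radius with a smooth
    groove carved into it.  The groove floor is not parallel to the flexion axis: its centre
    drifts laterally by ``trochlea_groove_obliquity`` mm per radian of
    patch angle ``phi`` (the oblique/helical course of the human trochlear
    groove, which couples flexion to valgus-internal loading of the
    pronated forearm).  ``phi = 0`` faces the sigmoid notch at the
    reference pose.
    """
    x = np.asarray(x, dtype=float)
    half = cfg.trochlea_width / 2.0
    u = np.clip((x - groove_drift(phi, cfg)) / half, -1.0, 1.0)
    depth = cfg.trochlea_groove_depth * np.cos(0.5 * np.pi * u) ** 2
    return cfg.trochlea_radius - depth + _flange(x)


def trochlea_profile_slope(x, cfg: GeometryConfig, phi=0.0):
    """d r / d x of the oblique groove profile (zero beyond the groove lips)."""
    x = np.asarray(x, dtype=float)
    half = cfg.trochlea_width / 2.0
    u = (x - groove_drift(phi, cfg)) / half
    inside = np.abs(u) < 1.0
    slope = cfg.trochlea_groove_depth * 0.5 * np.pi * np.sin(np.pi * np.clip(u, -1, 1)) / half
    return np.where(inside, slope, 0.0) + _flange_slope(x)


def trochlea_patch_area(cfg: GeometryConfig, phi_span_deg: float = 300.0,
                        phi_start_deg: float = -80.0) -> float:
    """Analytic area of the trochlear cartilage patch.

    Surface element of the oblique-grooved spool rho(x, phi):
    dA = sqrt(rho^2 (1 + rho_x^2) + rho_phi^2) dx dphi, integrated with
    Gauss-Legendre quadrature in both directions.
    """
    half = cfg.trochlea_width / 2.0
    xs, wx = np.polynomial.legendre.leggauss(24)
    xs = xs * half
    wx = wx * half
    p0 = math.radians(phi_start_deg)
    span = math.radians(phi_span_deg)
    ps, wp = np.polynomial.legendre.leggauss(24)
    ps = p0 + span / 2.0 + ps * span / 2.0
    wp = wp * span / 2.0
    X, P = np.meshgrid(xs, ps, indexing="ij")
    rho = trochlea_profile(X, cfg, P)
    rho_x = trochlea_profile_slope(X, cfg, P)
    rho_p = -groove_drift_rate(P, cfg) * rho_x
    integrand = np.sqrt(rho**2 * (1.0 + rho_x**2) + rho_p**2)
    return float(np.einsum("i,j,ij->", wx, wp, integrand))


def capitellum_patch_area(cfg: GeometryConfig, cap_half_angle_deg: float = 75.0) -> float:
    """Spherical-cap area of the capitellar cartilage patch."""
    r = cfg.capitellum_radius
    return 2.0 * math.pi * r**2 * (1.0 - math.cos(math.radians(cap_half_angle_deg)))


# angular extent of the trochlear cartilage patch, humerus frame.  phi is
# measured in the y-z plane from the -z (distal) direction toward +y
# (anterior); the patch covers distal-through-anterior-through-proximal,
# which is the region the sigmoid notch sweeps over the 45-135 degree
# flexion range, plus a posterior-distal margin.
_TROCHLEA_PHI_START = -80.0   # degrees, posterior-distal margin
_TROCHLEA_PHI_SPAN = 300.0
_CAPITELLUM_CAP_HALF_ANGLE = 75.0   # around the +y (anterior) axis


def _phi_dir(phi: np.ndarray) -> np.ndarray:
    """Unit direction in the y-z plane for patch angle phi (radians)."""
    # phi = 0 -> -z (distal); increasing phi rotates toward +y (anterior)
    return np.stack([np.zeros_like(phi), np.sin(phi), -np.cos(phi)], axis=-1)


# --------------------------------------------------------------------------
# cartilage discretization
# --------------------------------------------------------------------------

def _discretize_trochlea(cfg: GeometryConfig) -> list[ContactElement]:
    half = cfg.trochlea_width / 2.0
    edge = cfg.element_edge
    nx = max(1, round(cfg.trochlea_width / edge))
    r_mid = cfg.trochlea_radius - cfg.trochlea_groove_depth / 2.0
    span = math.radians(_TROCHLEA_PHI_SPAN)
    nphi = max(1, round(r_mid * span / edge))

    elements: list[ContactElement] = []
    xs_edges = np.linspace(-half, half, nx + 1)
    phi_edges = math.radians(_TROCHLEA_PHI_START) + np.linspace(0.0, span, nphi + 1)
    for i in range(nx):
        x0, x1 = xs_edges[i], xs_edges[i + 1]
        xm = 0.5 * (x0 + x1)
        for j in range(nphi):
            p0, p1 = phi_edges[j], phi_edges[j + 1]
            pm = 0.5 * (p0 + p1)
            rho = float(trochlea_profile(xm, cfg, pm))
            rho_x = float(trochlea_profile_slope(xm, cfg, pm))
            rho_p = -float(groove_drift_rate(pm, cfg)) * rho_x
            e_rho = _phi_dir(np.array(pm))
            e_phi = np.array([0.0, math.cos(pm), math.sin(pm)])
            center = np.array([xm, 0.0, 0.0]) + rho * e_rho
            normal = rho * e_rho - rho * rho_x * np.array([1.0, 0.0, 0.0]) - rho_p * e_phi
            jac = math.sqrt(rho**2 * (1.0 + rho_x**2) + rho_p**2)
            area = jac * (p1 - p0) * (x1 - x0)
            elements.append(
                ContactElement(
                    id=-1,
                    center=center,
                    normal=normal / np.linalg.norm(normal),
                    area=float(area),
                    map_uv=(float(xm), float(r_mid * pm)),
                    region="trochlea",
                )
            )
    return elements


def _discretize_capitellum(cfg: GeometryConfig) -> list[ContactElement]:
    """Polar grid on the spherical cap facing anterior (+y)."""
    edge = cfg.element_edge
    R = cfg.capitellum_radius
    cap = math.radians(_CAPITELLUM_CAP_HALF_ANGLE)
    ntheta = max(1, round(R * cap / edge))
    theta_edges = np.linspace(0.0, cap, ntheta + 1)
    center_cap = np.array([cfg.capitellum_offset, 0.0, 0.0])
    axis = np.array([0.0, 1.0, 0.0])      # anterior
    # basis perpendicular to axis
    b1 = np.array([1.0, 0.0, 0.0])
    b2 = np.array([0.0, 0.0, 1.0])

    elements: list[ContactElement] = []
    for i in range(ntheta):
        t0, t1 = theta_edges[i], theta_edges[i + 1]
        tm = 0.5 * (t0 + t1)
        ring_len = 2.0 * math.pi * R * math.sin(tm) if i > 0 else 2.0 * math.pi * R * math.sin(0.5 * t1)
        nseg = 1 if i == 0 else max(1, round(ring_len / edge))
        ring_area = 2.0 * math.pi * R**2 * (math.cos(t0) - math.cos(t1))
        for j in range(nseg):
            psi = 2.0 * math.pi * (j + 0.5) / nseg
            d = math.cos(tm) * axis + math.sin(tm) * (math.cos(psi) * b1 + math.sin(psi) * b2)
            center = center_cap + R * d
            elements.append(
                ContactElement(
                    id=-1,
                    center=center,
                    normal=d.copy(),
                    area=float(ring_area / nseg),
                    # capitellum map placed to the lateral side of the trochlea strip
                    map_uv=(
                        float(cfg.trochlea_width / 2.0 + 5.0 + R * tm * math.cos(psi)),
                        float(R * tm * math.sin(psi)),
                    ),
                    region="capitellum",
                )
            )
    return elements


def discretize_cartilage(surface: trimesh.Trimesh, element_edge: float,
                         seed: int = 0) -> list[ContactElement]:
    """Tile a triangulated cartilage surface into ~``element_edge``² patches.

    General-mesh path used for user-supplied geometry: triangle barycentres
    are clustered (k-means, k = round(area / edge²)) and each cluster
    becomes one element carrying its aggregate area, the area-weighted
    normal and a 2-D map coordinate from a planar projection of the
    cluster centres.  The parametric generator uses exact grids instead
    (see :func:`generate_elbow`); both produce the same element contract.
    """
    if surface.faces.shape[0] == 0:
        raise ValueError("cannot discretize an empty surface")
    edge = float(element_edge)
    if edge <= 0:
        raise ValueError("element_edge must be > 0")
    total_area = float(surface.area)
    k = int(round(total_area / edge**2))
    if k < 1:
        log.warning(
            "surface area %.2f mm^2 smaller than one %g mm element; returning a single element",
            total_area, edge,
        )
        k = 1

    centers = surface.triangles_center
    areas = surface.area_faces
    normals = surface.face_normals

    if k == 1:
        labels = np.zeros(len(areas), dtype=int)
    else:
        from scipy.cluster.vq import kmeans2

        # deterministic area-weighted k-means on triangle barycentres
        rng = np.random.default_rng(seed)
        reps = np.maximum(1, np.round(areas / areas.mean()).astype(int))
        pts = np.repeat(centers, reps, axis=0)
        _, lab_rep = kmeans2(pts, k, minit="++", seed=rng, iter=50)
        # map back: label of each face = label of its first replicate
        idx = np.cumsum(np.concatenate([[0], reps[:-1]]))
        labels = lab_rep[idx]

    elements: list[ContactElement] = []
    # 2-D map coordinates: project cluster centres on the two principal axes
    mean = centers.mean(axis=0)
    _, _, vt = np.linalg.svd(centers - mean, full_matrices=False)
    if vt.shape[0] < 2:
        vt = np.vstack([vt, np.zeros((2 - vt.shape[0], 3))])
    uv_axes = vt[:2]

    for lab in range(int(labels.max()) + 1):
        mask = labels == lab
        if not mask.any():
            continue
        a = areas[mask]
        c = np.average(centers[mask], axis=0, weights=a)
        n = np.average(normals[mask], axis=0, weights=a)
        nn = np.linalg.norm(n)
        if nn == 0:
            n = normals[mask][0]
            nn = 1.0
        uv = (c - mean) @ uv_axes.T
        elements.append(
            ContactElement(
                id=len(elements),
                center=c,
                normal=n / nn,
                area=float(a.sum()),
                map_uv=(float(uv[0]), float(uv[1])),
                region="trochlea",
            )
        )
    return elements


# --------------------------------------------------------------------------
# meshes (I/O + visual representation of the analytic surfaces)
# --------------------------------------------------------------------------

def _revolution_mesh(cfg: GeometryConfig, radius_fn, nx=24, nphi=64,
                     phi_start=None, phi_span=None) -> trimesh.Trimesh:
    half = cfg.trochlea_width / 2.0
    phi0 = math.radians(_TROCHLEA_PHI_START if phi_start is None else phi_start)
    span = math.radians(_TROCHLEA_PHI_SPAN if phi_span is None else phi_span)
    xs = np.linspace(-half, half, nx)
    phis = phi0 + np.linspace(0.0, span, nphi)
    verts = []
    for x in xs:
        d = _phi_dir(phis)
        r = np.asarray(radius_fn(np.full(nphi, x), phis), dtype=float)
        verts.append(np.column_stack([np.full(nphi, x), np.zeros(nphi), np.zeros(nphi)]) + r[:, None] * d)
    verts = np.concatenate(verts, axis=0)
    faces = []
    for i in range(nx - 1):
        for j in range(nphi - 1):
            a = i * nphi + j
            b = a + 1
            c = a + nphi
            d2 = c + 1
            faces.append([a, b, d2])
            faces.append([a, d2, c])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def _sphere_patch_mesh(center, R, axis, half_angle_deg, n=24) -> trimesh.Trimesh:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(axis @ tmp) > 0.9:
        tmp = np.array([0.0, 0.0, 1.0])
    b1 = np.cross(axis, tmp)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis, b1)
    thetas = np.linspace(0.0, math.radians(half_angle_deg), n)
    psis = np.linspace(0.0, 2 * math.pi, n)
    verts = []
    for t in thetas:
        d = math.cos(t) * axis[None, :] + math.sin(t) * (
            np.cos(psis)[:, None] * b1[None, :] + np.sin(psis)[:, None] * b2[None, :]
        )
        verts.append(np.asarray(center)[None, :] + R * d)
    verts = np.concatenate(verts, axis=0)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n + 1])
            faces.append([a, a + n + 1, a + n])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def _shaft_mesh(p0, p1, radius, n=16) -> trimesh.Trimesh:
    """Capped cylinder between two points (bone shaft placeholder)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    h = np.linalg.norm(p1 - p0)
    mesh = trimesh.creation.cylinder(radius=radius, height=h, sections=n)
    # align +z of the canonical cylinder with p1-p0
    direction = (p1 - p0) / h
    T = trimesh.geometry.align_vectors([0, 0, 1], direction)
    mesh.apply_transform(T)
    mesh.apply_translation((p0 + p1) / 2.0)
    return mesh


# --------------------------------------------------------------------------
# landmarks & atlas
# --------------------------------------------------------------------------

def _rx(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _landmarks(cfg: GeometryConfig, jitter) -> dict[str, dict[str, np.ndarray]]:
    Lh, Lu = cfg.humerus_length, cfg.ulna_length
    w = cfg.trochlea_width
    xc = cfg.capitellum_offset
    hum = {
        "trochlea_center": np.zeros(3),
        "capitellum_center": np.array([xc, 0.0, 0.0]),
        "medial_epicondyle": np.array([-(w / 2.0 + 7.0), 0.0, 2.0]),
        "lateral_epicondyle": np.array([xc + cfg.capitellum_radius + 2.5, -1.0, 6.0]),
        "humeral_head": np.array([0.0, 0.0, Lh]),
        "triceps_origin": np.array([-3.0, -18.0, 120.0]),
        "brachialis_origin": np.array([0.0, 14.0, 100.0]),
    }
    uln = {
        "notch_center": np.zeros(3),
        "coronoid_tip": np.array([0.0, 13.0, -4.0]),
        "olecranon_tip": np.array([0.0, -12.0, 10.0]),
        "sublime_tubercle": np.array([-10.0, 3.0, -5.0]),
        "medial_olecranon": np.array([-8.0, -1.5, 1.0]),
        "supinator_crest": np.array([9.0, 9.0, -22.0]),
        "radial_notch_anterior": np.array([9.0, 8.0, -10.0]),
        "radial_notch_posterior": np.array([9.0, -8.0, -10.0]),
        "io_proximal": np.array([3.0, 6.0, -60.0]),
        "io_distal": np.array([0.0, -6.0, -150.0]),
        "ulna_styloid": np.array([0.0, 0.0, -Lu]),
    }
    rad = {
        "radial_head_center": np.zeros(3),
        "head_rim_lateral": np.array([cfg.radial_head_radius - 1.0, -3.0, -2.0]),
        "io_proximal": np.array([-6.0, 6.0, -50.0]),
        "io_distal": np.array([-10.0, -6.0, -140.0]),
        "radial_styloid": np.array([-2.0, 0.0, -(cfg.radius_length - 10.0)]),
        "wrist_center": np.array([-2.0, 0.0, -(cfg.radius_length - 10.0)]),
    }
    out = {"humerus": hum, "ulna": uln, "radius": rad}
    for body in out.values():
        for name, p in body.items():
            body[name] = p + jitter()
    # frame-defining landmarks stay exact so that anatomical frames are
    # strictly reproducible references; the jitter models digitisation
    # scatter of the soft-tissue points only
    out["humerus"]["trochlea_center"] = np.zeros(3)
    out["humerus"]["humeral_head"] = np.array([0.0, 0.0, Lh])
    out["ulna"]["notch_center"] = np.zeros(3)
    out["ulna"]["ulna_styloid"] = np.array([0.0, 0.0, -Lu])
    return out


def _spread(base: np.ndarray, axis: np.ndarray, offsets) -> list[np.ndarray]:
    return [base + o * axis for o in offsets]


def _atlas(cfg: GeometryConfig, lm, jitter) -> dict[str, Attachment]:
    hum, uln, rad = lm["humerus"], lm["ulna"], lm["radius"]
    ME, LE = hum["medial_epicondyle"], hum["lateral_epicondyle"]
    ey = np.array([0.0, 1.0, 0.0])

    cap_sphere = WrapPrimitive(
        kind="sphere", body="humerus",
        point=tuple(hum["capitellum_center"]), radius=cfg.capitellum_radius + 0.3,
    )
    # the annular band hugs the radial head; the wrap cylinder is kept
    # well inside the rim ring so the endpoints stay outside it through the
    # full deformation range of the deficiency scenarios
    head_cyl = WrapPrimitive(
        kind="cylinder", body="radius",
        point=(0.0, 0.0, 0.0), radius=0.55 * cfg.radial_head_radius,
        axis=(0.0, 0.0, 1.0),
    )

    atlas: dict[str, Attachment] = {}

    def add(name, complex_, ob, o, ib, i, wraps=()):
        atlas[name] = Attachment(
            complex=complex_, origin_body=ob, origin=np.asarray(o, float) + jitter(),
            insertion_body=ib, insertion=np.asarray(i, float) + jitter(),
            wraps=tuple(wraps),
        )

    # MCL anterior bundle: medial epicondyle -> sublime tubercle (straight)
    for k, (o, i) in enumerate(zip(
        _spread(ME, ey, (3.0, 0.0, -3.0)),
        _spread(uln["sublime_tubercle"], ey, (2.0, 0.0, -2.0)),
    )):
        add(f"MCL_AB_{k + 1}", "MCL_AB", "humerus", o, "ulna", i)

    # MCL posterior bundle: medial epicondyle -> medial olecranon (straight)
    for k, (o, i) in enumerate(zip(
        _spread(ME, ey, (0.0, -2.0, -4.0)),
        _spread(uln["medial_olecranon"], ey, (2.0, 0.0, -2.0)),
    )):
        add(f"MCL_PB_{k + 1}", "MCL_PB", "humerus", o, "ulna", i)

    # LUCL: lateral epicondyle -> supinator crest, wrapped over the capitellum
    for k, (o, i) in enumerate(zip(
        _spread(LE, ey, (2.0, 0.0, -2.0)),
        _spread(uln["supinator_crest"], ey, (2.0, 0.0, -2.0)),
    )):
        add(f"LUCL_{k + 1}", "LUCL", "humerus", o, "ulna", i, wraps=(cap_sphere,))

    # RCL: lateral epicondyle -> lateral rim of the radial head (straight)
    for k, (o, i) in enumerate(zip(
        _spread(LE, ey, (2.5, 0.0, -2.5)),
        _spread(rad["head_rim_lateral"], ey, (2.0, 0.0, -2.0)),
    )):
        add(f"RCL_{k + 1}", "RCL", "humerus", o, "radius", i)

    # annular ligament: ulnar radial-notch rims, wrapped around the head
    add("annular_1", "annular", "ulna", uln["radial_notch_anterior"],
        "ulna", uln["radial_notch_posterior"], wraps=(head_cyl,))
    add("annular_2", "annular", "ulna",
        uln["radial_notch_anterior"] + np.array([0.0, 0.0, -3.0]),
        "ulna", uln["radial_notch_posterior"] + np.array([0.0, 0.0, -3.0]),
        wraps=(head_cyl,))
    return atlas


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def radial_head_offset(cfg: GeometryConfig) -> np.ndarray:
    """Radial head centre in the *ulna* frame at the nested reference pose."""
    th = math.radians(cfg.initial_flexion)
    d_world = _rx(th) @ np.array([0.0, 0.0, -1.0])      # forearm distal direction
    center_world = np.array([cfg.capitellum_offset, 0.0, 0.0]) + (
        cfg.capitellum_radius + cfg.notch_clearance
    ) * d_world
    return _rx(th).T @ center_world


def generate_elbow(config: GeometryConfig) -> ElbowGeometry:
    """Build the complete synthetic right elbow for ``config``.

    Deterministic: the same config (including seed) always yields bitwise
    identical arrays.  The attachment atlas contains the canonical fourteen
    bundles: three each for the MCL anterior band, MCL posterior band,
    LUCL and RCL, and two for the annular ligament.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    def jitter():
        # +-0.2 mm digitisation scatter on soft-tissue points
        return rng.uniform(-0.2, 0.2, size=3)

    lm = _landmarks(config, jitter)
    atlas = _atlas(config, lm, jitter)

    elements = _discretize_trochlea(config) + _discretize_capitellum(config)
    for i, e in enumerate(elements):
        e.id = i

    # articular (cartilage) surface meshes
    cart = {
        "trochlea": _revolution_mesh(
            config, lambda x, phi: trochlea_profile(x, config, phi)),
        "capitellum": _sphere_patch_mesh(
            lm["humerus"]["capitellum_center"], config.capitellum_radius,
            [0.0, 1.0, 0.0], _CAPITELLUM_CAP_HALF_ANGLE,
        ),
        "sigmoid_notch": _revolution_mesh(
            config,
            lambda x, phi: trochlea_profile(x, config) + config.notch_clearance,
            phi_start=-(config.sigmoid_notch_wrap_angle / 2.0) - 45.0,
            phi_span=config.sigmoid_notch_wrap_angle,
        ),
        "radial_dish": _sphere_patch_mesh(
            [0.0, 0.0, config.capitellum_radius + config.notch_clearance],
            config.capitellum_radius + config.notch_clearance,
            [0.0, 0.0, -1.0], config.radial_dish_cap_angle,
        ),
    }

    # bone shafts: simple capped cylinders carrying the long axes (for
    # export/visualisation; contact never queries them)
    bones = {
        "humerus": _shaft_mesh([0.0, 0.0, 8.0], lm["humerus"]["humeral_head"], 12.0),
        "ulna": _shaft_mesh([0.0, 0.0, -8.0], lm["ulna"]["ulna_styloid"], 8.0),
        "radius": _shaft_mesh([0.0, 0.0, -6.0], lm["radius"]["radial_styloid"], 7.0),
    }

    return ElbowGeometry(
        config=config,
        bone_meshes=bones,
        cartilage_meshes=cart,
        contact_elements=elements,
        attachments=atlas,
        landmarks=lm,
    )


# --------------------------------------------------------------------------
# persistence: STL/OBJ meshes + JSON atlas document
# --------------------------------------------------------------------------

def save_geometry(geom: ElbowGeometry, out_dir: str | Path,
                  mesh_format: str = "stl") -> dict[str, str]:
    """Write meshes and the atlas/landmark JSON document; returns file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for group, meshes in (("bone", geom.bone_meshes), ("cartilage", geom.cartilage_meshes)):
        for name, mesh in meshes.items():
            path = out / f"{group}_{name}.{mesh_format}"
            mesh.export(path)
            written[f"{group}_{name}"] = str(path)

    doc = {
        "config": dataclasses.asdict(geom.config),
        "landmarks": {
            body: {k: list(map(float, v)) for k, v in pts.items()}
            for body, pts in geom.landmarks.items()
        },
        "attachments": {
            name: {
                "complex": a.complex,
                "origin_body": a.origin_body,
                "origin": list(map(float, a.origin)),
                "insertion_body": a.insertion_body,
                "insertion": list(map(float, a.insertion)),
                "wraps": [
                    {
                        "kind": w.kind, "body": w.body, "point": list(w.point),
                        "radius": w.radius,
                        "axis": list(w.axis) if w.axis is not None else None,
                    }
                    for w in a.wraps
                ],
            }
            for name, a in geom.attachments.items()
        },
    }
    atlas_path = out / "atlas.json"
    atlas_path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    written["atlas"] = str(atlas_path)
    return written


def load_atlas(path: str | Path):
    """Read back the JSON atlas document written by :func:`save_geometry`.

    Returns ``(config, attachments, landmarks)``.
    """
    doc = json.loads(Path(path).read_text())
    config = GeometryConfig(**doc["config"])
    landmarks = {
        body: {k: np.asarray(v, float) for k, v in pts.items()}
        for body, pts in doc["landmarks"].items()
    }
    attachments = {
        name: Attachment(
            complex=a["complex"],
            origin_body=a["origin_body"], origin=np.asarray(a["origin"], float),
            insertion_body=a["insertion_body"], insertion=np.asarray(a["insertion"], float),
            wraps=tuple(
                WrapPrimitive(
                    kind=w["kind"], body=w["body"], point=tuple(w["point"]),
                    radius=w["radius"],
                    axis=tuple(w["axis"]) if w["axis"] is not None else None,
                )
                for w in a["wraps"]
            ),
        )
        for name, a in doc["attachments"].items()
    }
    return config, attachments, landmarks
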