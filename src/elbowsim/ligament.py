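"""Nonlinear ligament bundle mechanics with wrapping and sectioning.

Each collateral-ligament bundle is a tension-only force element between a
body-anchored origin and insertion.  The elastic force-strain law has a
quadratic "toe" region blending into a linear region,

    f(eps) = k * eps**2 / (4 * eps_l)    for 0 <= eps <= 2 eps_l
    f(eps) = k * (eps - eps_l)           for eps > 2 eps_l
    f(eps) = 0                           for eps < 0 (slack)

with engineering strain ``eps = (l - l0) / l0`` about the zero-load length
``l0``.  The two branches meet with matching value (k * eps_l) and slope
(k) at eps = 2 eps_l, so the law is C1 across the toe.  A parallel damper
(default 0.5 Ns/mm) suppresses high-frequency length oscillation; the
total bundle force is clamped at zero from below because a ligament cannot
push.

LUCL and annular bundles route around convex bone primitives (sphere or
cylinder) so their lines of action stay anatomical through the flexion
arc; :func:`wrap_route` returns the shortest obstacle-avoiding path length
together with the departing unit tangents at both endpoints, which is all
the force model needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Attachment, WrapPrimitive

__all__ = [
    "LigamentBundle",
    "LigamentState",
    "SCENARIOS",
    "engineering_strain",
    "bundle_elastic_force",
    "bundle_elastic_energy",
    "bundle_total_force",
    "wrap_route",
    "section_bundles",
    "build_bundles",
    "DEFAULT_STIFFNESS",
    "DEFAULT_PRETENSION",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class LigamentBundle:
    """Constitutive and geometric description of one ligament bundle."""

    name: str
    complex: str                 # MCL_AB | MCL_PB | LUCL | RCL | annular
    origin_body: str
    origin: np.ndarray           # local coords on origin body, mm
    insertion_body: str
    insertion: np.ndarray
    k: float                     # stiffness parameter, N per unit strain
    eps_l: float = 0.03          # toe-region spring parameter
    l0: float = 1.0              # zero-load length, mm
    c: float = 0.5               # parallel damping, Ns/mm
    wraps: tuple[WrapPrimitive, ...] = ()
    active: bool = True

    def validate(self) -> None:
        if not self.l0 > 0:
            raise ValueError(f"bundle {self.name}: l0 must be > 0, got {self.l0!r}")
        if self.k < 0:
            raise ValueError(f"bundle {self.name}: k must be >= 0")
        if not self.eps_l > 0:
            raise ValueError(f"bundle {self.name}: eps_l must be > 0")
        if self.c < 0:
            raise ValueError(f"bundle {self.name}: c must be >= 0")


@dataclass
class LigamentState:
    """Instantaneous kinematic/kinetic state of one bundle."""

    l: float          # current path length, mm
    l_dot: float      # lengthening rate, mm/s
    eps: float        # engineering strain
    f: float          # tensile force, N (>= 0)


# --------------------------------------------------------------------------
# constitutive closed forms
# --------------------------------------------------------------------------

def engineering_strain(l, l0):
    """Engineering strain (l - l0) / l0; ``l0`` must be positive."""
    l0 = np.asarray(l0, dtype=float)
    if np.any(l0 <= 0):
        raise ValueError(f"zero-load length must be > 0, got {l0!r}")
    out = (np.asarray(l, dtype=float) - l0) / l0
    return out.item() if out.ndim == 0 else out


def bundle_elastic_force(eps, k, eps_l):
    """Tension-only toe-region elastic force, N.  Accepts scalars or arrays."""
    if not eps_l > 0:
        raise ValueError(f"eps_l must be > 0, got {eps_l!r}")
    eps = np.asarray(eps, dtype=float)
    toe = 0.25 * k * eps**2 / eps_l
    linear = k * (eps - eps_l)
    out = np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * eps_l, toe, linear))
    return out.item() if out.ndim == 0 else out


def bundle_elastic_energy(eps, k, eps_l, l0):
    """Stored elastic energy, N*mm: integral of f over length change.

    The quasistatic solver minimises total potential energy, so the energy
    must be the exact antiderivative of :func:`bundle_elastic_force` (times
    ``l0``, since d l = l0 d eps).
    """
    eps = np.asarray(eps, dtype=float)
    toe = k * eps**3 / (12.0 * eps_l)
    u_2el = 2.0 * k * eps_l**2 / 3.0
    linear = u_2el + 0.5 * k * ((eps - eps_l) ** 2 - eps_l**2)
    out = l0 * np.where(eps <= 0.0, 0.0, np.where(eps <= 2.0 * eps_l, toe, linear))
    return out.item() if out.ndim == 0 else out


def bundle_total_force(state: LigamentState, bundle: LigamentBundle) -> float:
    """Elastic plus parallel-damper force, clamped at zero (no pushing)."""
    if not bundle.active:
        return 0.0
    f = bundle_elastic_force(state.eps, bundle.k, bundle.eps_l) + bundle.c * state.l_dot
    return max(float(f), 0.0)


# --------------------------------------------------------------------------
# wrapping
# --------------------------------------------------------------------------

def _circle_wrap_2d(p, q, r):
    """Shortest path around the disk of radius r at the origin, in 2-D.

    Returns ``(length, t_p, t_q, wrapped, arc)`` where ``t_p``/``t_q`` are
    the unit departing directions of the path at p and q and ``arc`` is the
    wrapped arc angle (which is also dL/dr, by the envelope theorem).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dp = math.sqrt(float(p @ p))
    dq = math.sqrt(float(q @ q))
    if dp <= r or dq <= r:
        raise ValueError("endpoint inside wrapping circle")

    straight = q - p
    ls = math.sqrt(float(straight @ straight))

    # distance from origin to the segment pq
    t = min(1.0, max(0.0, -float(p @ straight) / (ls * ls))) if ls > 0 else 0.0
    closest = p + t * straight
    if math.sqrt(float(closest @ closest)) >= r or ls == 0.0:
        u = straight / ls if ls > 0 else np.array([1.0, 0.0])
        return ls, u, -u, False, 0.0

    ap = math.acos(min(1.0, r / dp))    # half-aperture of the tangent cone at p
    aq = math.acos(min(1.0, r / dq))
    cosang = float(np.clip((p @ q) / (dp * dq), -1.0, 1.0))
    theta = math.acos(cosang)
    arc = theta - ap - aq
    if arc <= 0.0:
        u = straight / ls
        return ls, u, -u, False, 0.0

    side = math.copysign(1.0, p[0] * q[1] - p[1] * q[0])
    if side == 0.0:
        side = 1.0

    def rot(v, a):
        c, s = math.cos(a), math.sin(a)
        return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])

    tp_point = r * rot(p / dp, side * ap)
    tq_point = r * rot(q / dq, -side * aq)
    lp = math.sqrt(dp * dp - r * r)
    lq = math.sqrt(dq * dq - r * r)
    length = lp + lq + r * arc
    t_p = (tp_point - p) / lp
    t_q = (tq_point - q) / lq
    return length, t_p, t_q, True, arc


def _wrap_sphere(a, b, center, r):
    """Shortest path around a sphere; the geodesic lies in the plane (a, b, c)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(center, dtype=float)
    pa, pb = a - c, b - c
    la = math.sqrt(float(pa @ pa))
    lb = math.sqrt(float(pb @ pb))
    e1 = pa / la
    n = np.array([pa[1] * pb[2] - pa[2] * pb[1],
                  pa[2] * pb[0] - pa[0] * pb[2],
                  pa[0] * pb[1] - pa[1] * pb[0]])
    if math.sqrt(float(n @ n)) < 1e-9 * la * max(lb, 1.0):
        # (near-)antipodal endpoints: any plane through the line is geodesic
        probe = np.array([1.0, 0.0, 0.0])
        if abs(e1[0]) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.array([e1[1] * probe[2] - e1[2] * probe[1],
                      e1[2] * probe[0] - e1[0] * probe[2],
                      e1[0] * probe[1] - e1[1] * probe[0]])
    n = n / math.sqrt(float(n @ n))
    e2 = np.array([n[1] * e1[2] - n[2] * e1[1],
                   n[2] * e1[0] - n[0] * e1[2],
                   n[0] * e1[1] - n[1] * e1[0]])

    def to2(v):
        return np.array([v @ e1, v @ e2])

    length, t2p, t2q, wrapped, arc = _circle_wrap_2d(to2(pa), to2(pb), r)

    def to3(v2):
        return v2[0] * e1 + v2[1] * e2

    return length, to3(t2p), to3(t2q), wrapped, arc


def _wrap_cylinder(a, b, point, axis, r):
    """Shortest path around an infinite cylinder (development construction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p0 = np.asarray(point, dtype=float)
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    probe = np.array([1.0, 0.0, 0.0])
    if abs(w @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(w, probe)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(w, e1)

    def split(v):
        rel = v - p0
        return np.array([rel @ e1, rel @ e2]), float(rel @ w)

    a2, za = split(a)
    b2, zb = split(b)
    l2, t2a, t2b, wrapped, arc = _circle_wrap_2d(a2, b2, r)
    dz = zb - za
    if not wrapped:
        d = b - a
        ln = np.linalg.norm(d)
        u = d / ln if ln > 0 else w
        return ln, u, -u, False, 0.0
    length = math.hypot(l2, dz)

    def lift(t2, zsign):
        planar = t2[0] * e1 + t2[1] * e2
        d = planar * (l2 / length) + w * (zsign * dz / length)
        return d / np.linalg.norm(d)

    # dL/dr = (l2 / L) * d l2 / dr, with d l2 / dr = planar arc angle
    return length, lift(t2a, 1.0), lift(t2b, -1.0), True, (l2 / length) * arc


def wrap_route(origin, insertion, primitives, strict: bool = True):
    """Shortest origin-to-insertion path avoiding convex primitives.

    All points and primitives must be expressed in one common frame.
    Returns ``(length, tangent_at_origin, tangent_at_insertion, wrapped)``
    where the tangents are the negative gradients of the path length with
    respect to each endpoint: unit vectors pointing from the endpoint along
    the path in the regular regime.  With no primitives (or none engaged)
    this is the straight segment.  Only one primitive engages per bundle in
    this model; with several, the first engaged one (in order) is used.

    An endpoint inside a primitive is a modelling error and raises (the
    message identifies the primitive).  ``strict=False`` — used by the
    solver while it explores trial configurations — instead shrinks the
    effective obstacle radius just below the endpoint distance, keeping
    the path length finite and continuous through the excursion; in that
    regime the returned endpoint vectors include the radius-sensitivity
    term (dL/dr = wrapped arc), so force models built on them stay
    consistent with the length.
    """
    origin = np.asarray(origin, dtype=float)
    insertion = np.asarray(insertion, dtype=float)
    for prim in primitives:
        center = np.asarray(prim.point, dtype=float)
        if prim.kind == "sphere":
            ca = float(np.linalg.norm(origin - center))
            cb = float(np.linalg.norm(insertion - center))
            rad_a = (origin - center) / ca if ca > 0 else np.zeros(3)
            rad_b = (insertion - center) / cb if cb > 0 else np.zeros(3)
        elif prim.kind == "cylinder":
            w = np.asarray(prim.axis, dtype=float)
            w = w / np.linalg.norm(w)
            pa = (origin - center) - ((origin - center) @ w) * w
            pb = (insertion - center) - ((insertion - center) @ w) * w
            ca, cb = float(np.linalg.norm(pa)), float(np.linalg.norm(pb))
            rad_a = pa / ca if ca > 0 else np.zeros(3)
            rad_b = pb / cb if cb > 0 else np.zeros(3)
        else:
            raise ValueError(f"unknown wrap primitive kind {prim.kind!r}")

        clearance = min(ca, cb)
        r = prim.radius
        shrunk = False
        if clearance <= r and strict:
            raise ValueError(f"ligament endpoint inside wrap primitive {prim!r}")
        if not strict and 0.99 * clearance < r:
            # continuous shrink keeps the path length well defined (and the
            # energy continuous) through grazing trial configurations
            r = 0.99 * clearance
            shrunk = True
            if r <= 1e-9:
                continue
        if prim.kind == "sphere":
            length, tp, tq, wrapped, dldr = _wrap_sphere(origin, insertion, center, r)
        else:
            length, tp, tq, wrapped, dldr = _wrap_cylinder(
                origin, insertion, center, prim.axis, r
            )
        if wrapped:
            if shrunk and dldr != 0.0:
                # r tracks the governing endpoint: fold dL/dr into its
                # returned vector so  t = -dL/d(endpoint)  remains exact
                if ca <= cb:
                    tp = tp - 0.99 * dldr * rad_a
                else:
                    tq = tq - 0.99 * dldr * rad_b
            return length, tp, tq, True

    d = insertion - origin
    ln = float(np.linalg.norm(d))
    u = d / ln if ln > 0 else np.array([1.0, 0.0, 0.0])
    return ln, u, -u, False


# --------------------------------------------------------------------------
# sectioning scenarios
# --------------------------------------------------------------------------

#: scenario -> set of ligament complexes removed
SCENARIOS: dict[str, frozenset[str]] = {
    "intact": frozenset(),
    "MCL_AB_deficient": frozenset({"MCL_AB"}),
    "MCL_PB_deficient": frozenset({"MCL_PB"}),
    "both_MCL_deficient": frozenset({"MCL_AB", "MCL_PB"}),
}


def section_bundles(atlas: dict[str, LigamentBundle], scenario: str) -> dict[str, LigamentBundle]:
    """Deactivate the bundles of the sectioned complex(es).

    Returns a new atlas; all other bundles are untouched and the operation
    is idempotent.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid scenarios: {sorted(SCENARIOS)}"
        )
    removed = SCENARIOS[scenario]
    return {
        name: replace(b, active=b.active and b.complex not in removed)
        for name, b in atlas.items()
    }


# --------------------------------------------------------------------------
# bundle construction from the attachment atlas
# --------------------------------------------------------------------------

#: per-bundle stiffness defaults (N per unit strain).  Calibration values
#: for the synthetic elbow, chosen so the intact simulation produces peak
#: complex loads of tens-to-hundreds of Newtons and maximum strains in the
#: 0.1-0.5 band typical of collateral ligament bundles; not subject data.
DEFAULT_STIFFNESS: dict[str, float] = {
    "MCL_AB": 500.0,
    "MCL_PB": 150.0,
    "LUCL": 250.0,
    "RCL": 150.0,
    "annular": 150.0,
}

#: reference-pose pretension strain per complex: the zero-load length is
#: the generated path length at the reference pose divided by
#: (1 + pretension), standing in for the cadaveric zero-load-length
#: protocol the original models used.
DEFAULT_PRETENSION: dict[str, float] = {
    "MCL_AB": 0.09,
    "MCL_PB": 0.03,
    "LUCL": 0.02,
    "RCL": 0.02,
    "annular": 0.0,
}


def build_bundles(
    attachments: dict[str, Attachment],
    reference_lengths: dict[str, float],
    stiffness: dict[str, float] | None = None,
    pretension: dict[str, float] | None = None,
    eps_l: float = 0.03,
    damping: float = 0.5,
) -> dict[str, LigamentBundle]:
    """Assemble constitutive bundles from the geometric atlas.

    ``reference_lengths`` are the bundle path lengths at the generation
    reference pose; zero-load lengths follow from the per-complex
    pretension strains.
    """
    stiffness = {**DEFAULT_STIFFNESS, **(stiffness or {})}
    pretension = {**DEFAULT_PRETENSION, **(pretension or {})}
    bundles: dict[str, LigamentBundle] = {}
    for name, att in attachments.items():
        pre = pretension[att.complex]
        l_ref = reference_lengths[name]
        bundle = LigamentBundle(
            name=name,
            complex=att.complex,
            origin_body=att.origin_body,
            origin=np.asarray(att.origin, float),
            insertion_body=att.insertion_body,
            insertion=np.asarray(att.insertion, float),
            k=stiffness[att.complex],
            eps_l=eps_l,
            l0=l_ref / (1.0 + pre),
            c=damping,
            wraps=att.wraps,
        )
        bundle.validate()
        bundles[name] = bundle
    return bundles
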