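"""Quasistatic multibody solve of passive elbow flexion.

The study rig is reproduced as four rigid bodies.  The humerus hangs
vertically and is driven: its head is tied to ground through a
translational (prismatic) joint, so the whole bone translates 345 mm
straight down over 40 s with fixed orientation.  The hand rests on the
plate through a soft six-degree-of-freedom spring (bushing); the wrist is
a spherical joint between the distal radius and the hand.  The ulna and
radius are otherwise held only by articular contact, the ligament bundles,
two constant muscle tensions (40 N triceps, 20 N brachialis) and gravity.
As the humeral head descends the elbow is forced to flex, sweeping the
45-135 degree arc.

The drive is slow (345 mm / 40 s), so the default solver treats the run
as a continuation of static equilibria parameterised by the prescribed
displacement: at each step the total potential energy (contact + ligament
+ muscle + gravity + bushing + joint penalties) is minimised over the 18
unconstrained coordinates (ulna, radius, hand; 6 each) with analytic
gradients, then polished by damped Newton until the generalized-force
residual drops below tolerance.  Velocity-dependent terms (the
penetration-dependent contact damper, the ligament parallel dampers) are
dissipative stabilisers of the original dynamic formulation; in the
quasistatic limit they carry no load and are evaluated for reporting from
finite-difference rates between accepted steps.  An overdamped implicit
"dynamic" mode (stiff BDF integration of the damped first-order system) is
available as a fidelity check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from . import contact as _contact
from . import ligament as _ligament
from .contact import ContactParameters, DishSurface, NotchSurface
from .geometry import ElbowGeometry, GeometryConfig
from .kinematics import BodyFrame, decompose_jcs, frame_from_landmarks
from .ligament import LigamentBundle, wrap_route

log = logging.getLogger(__name__)

__all__ = [
    "RigidBodyState",
    "JointConstraint",
    "MotionDrive",
    "ExternalLoad",
    "SimulationConfig",
    "SimulationTrace",
    "Body",
    "EnergyModel",
    "assemble_system",
    "run_flexion_sim",
    "default_joints",
    "solve_static",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class RigidBodyState:
    """Pose and twist of one body at one instant."""

    body: str
    position: np.ndarray                 # mm
    orientation: np.ndarray              # unit quaternion (x, y, z, w)
    linear_velocity: np.ndarray          # mm/s
    angular_velocity: np.ndarray         # rad/s

    def __post_init__(self):
        q = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"orientation quaternion of {self.body!r} is not unit (|q|={n})")


@dataclass(frozen=True)
class JointConstraint:
    """Declarative joint description consumed by :func:`assemble_system`."""

    type: str                      # translational | spherical | fixed | bushing6dof
    parent: str
    child: str
    axis: tuple[float, float, float] | None = None
    stiffness: tuple[float, ...] | None = None   # bushing: 3 translational N/mm + 3 rotational N*mm/rad
    penalty: float = 300.0                        # spherical joint penalty, N/mm
    rot_penalty: float = 400.0                    # wrist torsion transfer, N*mm/rad


def default_joints() -> list[JointConstraint]:
    """The study rig: driven humerus, wrist sphere, hand-ground bushing."""
    return [
        JointConstraint(type="translational", parent="ground", child="humerus",
                        axis=(0.0, 0.0, -1.0)),
        JointConstraint(type="spherical", parent="radius", child="hand", penalty=300.0),
        JointConstraint(type="bushing6dof", parent="ground", child="hand",
                        stiffness=(0.05, 0.05, 4.0, 200.0, 200.0, 200.0)),
    ]


@dataclass(frozen=True)
class MotionDrive:
    """Prescribed vertical humeral-head motion."""

    total_displacement: float = 345.0    # mm
    duration: float = 40.0               # s
    profile: str = "smoothed"            # linear | smoothed
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def displacement(self, t):
        if not self.duration > 0:
            raise ValueError("drive duration must be > 0")
        s = np.clip(np.asarray(t, dtype=float) / self.duration, 0.0, 1.0)
        if self.profile == "smoothed":
            s = s * s * (3.0 - 2.0 * s)
        elif self.profile != "linear":
            raise ValueError(f"unknown drive profile {self.profile!r}")
        out = self.total_displacement * s
        return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class ExternalLoad:
    """Constant muscle tensions and gravity switches.

    Muscle lines of action are straight segments between atlas anchor
    points; magnitudes stay constant through the run.  The biceps is not
    simulated.  Segment masses are standard anthropometric defaults; the
    forearm centres of mass sit slightly medial of the long axes, which is
    how the fixed fully-pronated posture (radius crossed over the ulna,
    palm down on the plate) loads this reduced segment model.
    """

    triceps: float = 40.0                 # N
    brachialis: float = 20.0              # N
    gravity: bool = True
    interosseous: bool = True             # membrane single force elements
    masses: dict = field(default_factory=lambda: {"ulna": 0.6, "radius": 0.5, "hand": 0.45})  # kg
    com_local: dict = field(default_factory=lambda: {
        "humerus": (0.0, 0.0, 150.0),
        "ulna": (-22.0, 10.0, -95.0),
        "radius": (-8.0, 0.0, -100.0),
        "hand": (0.0, 10.0, 0.0),
    })

    def validate(self):
        if self.triceps < 0 or self.brachialis < 0:
            raise ValueError("muscle tensions must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Solver settings for the flexion run."""

    solver: str = "quasistatic"          # quasistatic | dynamic
    n_steps: int = 160                   # drive discretization
    gtol: float = 1e-3                   # generalized-force residual, N / N*mm
    max_flexion: float = 135.0           # deg, early-termination bound
    max_step_halvings: int = 6
    separation_bound: float = 5.0        # mm, dislocation-candidate flag threshold
    seed: int = 0

    def validate(self):
        if self.solver not in ("quasistatic", "dynamic"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not self.gtol > 0:
            raise ValueError("gtol must be > 0")


@dataclass
class SimulationTrace:
    """Time series of the full system state over the flexion drive."""

    times: np.ndarray
    drive: np.ndarray
    flexion: np.ndarray                       # ulna F-E, deg
    positions: dict                           # body -> (n, 3)
    rotations: dict                           # body -> (n, 3, 3)
    ligament: dict                            # name -> {"l","eps","force"} (n,)
    contact_delta: dict                       # region -> (n, m)
    contact_force: dict                       # region -> (n, m)
    element_area: dict                        # region -> (m,)
    element_uv: dict                          # region -> (m, 2)
    residuals: np.ndarray
    iterations: np.ndarray
    dislocation_candidate: bool = False

    def n_samples(self) -> int:
        return len(self.times)

    def body_state(self, body: str, i: int) -> RigidBodyState:
        R = self.rotations[body][i]
        if i > 0:
            dt = self.times[i] - self.times[i - 1]
            v = (self.positions[body][i] - self.positions[body][i - 1]) / dt
            dR = self.rotations[body][i] @ self.rotations[body][i - 1].T
            w = Rotation.from_matrix(dR).as_rotvec() / dt
        else:
            v = np.zeros(3)
            w = np.zeros(3)
        return RigidBodyState(
            body=body, position=self.positions[body][i].copy(),
            orientation=Rotation.from_matrix(R).as_quat(),
            linear_velocity=v, angular_velocity=w,
        )

    def validate(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times are not strictly increasing")
        for arrs in (self.positions, self.rotations):
            for a in arrs.values():
                if not np.all(np.isfinite(a)):
                    raise ValueError("trace contains non-finite values")


# --------------------------------------------------------------------------
# rigid-body bookkeeping
# --------------------------------------------------------------------------

def _cross3(a, b):
    """3-vector cross product without numpy's dispatch overhead."""
    return np.array([
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    ])


def _rodrigues(theta):
    """exp of a rotation vector, closed form."""
    t2 = float(theta @ theta)
    if t2 < 1e-16:
        K = _skew(theta)
        return np.eye(3) + K + 0.5 * (K @ K)
    t = math.sqrt(t2)
    K = _skew(theta / t)
    return np.eye(3) + math.sin(t) * K + (1.0 - math.cos(t)) * (K @ K)


def _rotvec_from_matrix(R):
    """Rotation vector of a proper rotation matrix (closed form)."""
    tr = R[0, 0] + R[1, 1] + R[2, 2]
    cos_t = max(-1.0, min(1.0, 0.5 * (tr - 1.0)))
    axis_raw = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_t = 0.5 * math.sqrt(max(0.0, float(axis_raw @ axis_raw)))
    t = math.atan2(sin_t, cos_t)
    if sin_t < 1e-7:
        if cos_t > 0.0:
            return 0.5 * axis_raw       # small angle
        # near pi: fall back to the robust library path
        return Rotation.from_matrix(R).as_rotvec()
    return axis_raw * (0.5 * t / sin_t)


def _skew(v):
    return np.array([
        [0.0, -v[2], v[1]],
        [v[2], 0.0, -v[0]],
        [-v[1], v[0], 0.0],
    ])


def _exp_so3(theta):
    return Rotation.from_rotvec(theta).as_matrix()


def _left_jacobian(theta):
    """Left Jacobian of SO(3): d(exp) for world-frame angular variations."""
    t = np.linalg.norm(theta)
    K = _skew(theta)
    if t < 1e-8:
        return np.eye(3) + 0.5 * K + K @ K / 6.0
    return (
        np.eye(3)
        + ((1.0 - math.cos(t)) / t**2) * K
        + ((t - math.sin(t)) / t**3) * (K @ K)
    )


@dataclass
class Body:
    name: str
    prescribed: bool = False
    p_ref: np.ndarray = field(default_factory=lambda: np.zeros(3))
    R_ref: np.ndarray = field(default_factory=lambda: np.eye(3))
    weight: float = 0.0                   # N
    com_local: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class _ContactGroup:
    """Elements on one body against one analytic patch on another body."""

    element_body: str
    patch_body: str
    patch: object                          # .penetration(local pts) -> (delta, grad)
    centers_local: np.ndarray              # (m, 3)
    areas: np.ndarray                      # (m,)
    kc: np.ndarray                         # (m,) per-element stiffness N/mm
    params: ContactParameters
    region: str


@dataclass
class _Cable:
    """Point-to-point force element; ``kind`` selects the constitutive law."""

    kind: str                              # ligament | tension | linear
    a_body: str
    a_local: np.ndarray
    b_body: str
    b_local: np.ndarray
    bundle: LigamentBundle | None = None
    tension: float = 0.0                   # for kind == "tension"
    k: float = 0.0                         # for kind == "linear"
    rest: float = 0.0
    name: str = ""
    wraps: tuple = ()                      # pulley primitives (muscles)


@dataclass
class _Bushing:
    body: str
    p_ref: np.ndarray
    R_ref: np.ndarray
    k_t: np.ndarray                        # (3,) N/mm, world axes
    k_r: np.ndarray                        # (3,) N*mm/rad


@dataclass
class _RelRotSpring:
    """Isotropic rotational spring on the relative orientation of two bodies.

    Models torque transfer across a joint that the translational penalty
    alone cannot see (e.g. pronation moments through the carpus).
    """

    body_a: str
    body_b: str
    R_rel0: np.ndarray                     # reference R_a R_b^T
    k: float                               # N*mm/rad


class EnergyModel:
    """Total-potential model over the free-body coordinates.

    Free coordinates are step-local: each free body contributes a
    translation increment and a rotation vector about its current
    reference pose, re-centred at every accepted continuation step so the
    rotation parametrization never leaves the small-angle neighbourhood.
    """

    def __init__(self, bodies: dict[str, Body]):
        self.bodies = bodies
        self.free = [b.name for b in bodies.values() if not b.prescribed]
        self.index = {name: i for i, name in enumerate(self.free)}
        self.contacts: list[_ContactGroup] = []
        self.cables: list[_Cable] = []
        self.bushings: list[_Bushing] = []
        self.rot_springs: list[_RelRotSpring] = []
        self.gravity = True

    # -- pose handling ----------------------------------------------------

    @property
    def ndof(self) -> int:
        return 6 * len(self.free)

    def poses(self, q: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for name, body in self.bodies.items():
            if body.prescribed:
                out[name] = (body.p_ref, body.R_ref)
            else:
                i = self.index[name]
                dp = q[6 * i: 6 * i + 3]
                th = q[6 * i + 3: 6 * i + 6]
                out[name] = (body.p_ref + dp, _rodrigues(th) @ body.R_ref)
        return out

    def recenter(self, q: np.ndarray) -> None:
        """Fold the current increments into the reference poses."""
        for name in self.free:
            i = self.index[name]
            body = self.bodies[name]
            body.p_ref = body.p_ref + q[6 * i: 6 * i + 3]
            body.R_ref = _rodrigues(q[6 * i + 3: 6 * i + 6]) @ body.R_ref

    def world_point(self, poses, body: str, local) -> np.ndarray:
        p, R = poses[body]
        return p + R @ np.asarray(local, dtype=float)

    # -- energy and gradient ----------------------------------------------

    def energy(self, q: np.ndarray, detail: bool = False):
        poses = self.poses(q)
        V = 0.0
        forces = {name: np.zeros(3) for name in self.bodies}
        torques = {name: np.zeros(3) for name in self.bodies}
        info = {"ligament": {}, "contact": {}} if detail else None

        def apply(body, f, at):
            forces[body] += f
            torques[body] += _cross3(at - poses[body][0], f)

        # gravity
        if self.gravity:
            for name, body in self.bodies.items():
                if body.weight == 0.0:
                    continue
                com = self.world_point(poses, name, body.com_local)
                V += body.weight * com[2]
                apply(name, np.array([0.0, 0.0, -body.weight]), com)

        # contact groups
        for grp in self.contacts:
            pe, Re = poses[grp.element_body]
            pp, Rp = poses[grp.patch_body]
            x_world = pe + grp.centers_local @ Re.T
            y_local = (x_world - pp) @ Rp
            delta, grad = grp.patch.penetration(y_local)
            active = delta > 0.0
            if np.any(active):
                d = delta[active]
                kc = grp.kc[active]
                V += 0.5 * float(np.sum(kc * d * d))
                n_world = grad[active] @ Rp.T
                f_el = (kc * d)[:, None] * n_world      # on the patch body
                fp, tp = poses[grp.patch_body][0], poses[grp.element_body][0]
                xw = x_world[active]
                forces[grp.patch_body] += f_el.sum(axis=0)
                torques[grp.patch_body] += np.cross(xw - pp, f_el).sum(axis=0)
                forces[grp.element_body] += -f_el.sum(axis=0)
                torques[grp.element_body] += np.cross(xw - pe, -f_el).sum(axis=0)
            if detail:
                info["contact"][grp.region] = {
                    "delta": delta.copy(),
                    "elastic": np.where(delta > 0.0, grp.kc * np.maximum(delta, 0.0), 0.0),
                }

        # cables: ligaments, muscles, penalty springs
        for cab in self.cables:
            a_w = self.world_point(poses, cab.a_body, cab.a_local)
            b_w = self.world_point(poses, cab.b_body, cab.b_local)

            if cab.kind == "ligament":
                bundle = cab.bundle
                if bundle.wraps:
                    prim = bundle.wraps[0]
                    pw, Rw = poses[prim.body]
                    a_l = Rw.T @ (a_w - pw)
                    b_l = Rw.T @ (b_w - pw)
                    length, ta_l, tb_l, wrapped = wrap_route(a_l, b_l, bundle.wraps,
                                                             strict=False)
                    ta, tb = Rw @ ta_l, Rw @ tb_l
                else:
                    d = b_w - a_w
                    length = math.sqrt(float(d @ d))
                    ta = d / length if length > 0 else np.zeros(3)
                    tb = -ta
                    wrapped = False
                eps = (length - bundle.l0) / bundle.l0
                if bundle.active and eps > 0.0:
                    f = _ligament.bundle_elastic_force(eps, bundle.k, bundle.eps_l)
                    V += _ligament.bundle_elastic_energy(eps, bundle.k, bundle.eps_l, bundle.l0)
                else:
                    f = 0.0
                if f > 0.0:
                    apply(cab.a_body, f * ta, a_w)
                    apply(cab.b_body, f * tb, b_w)
                    if bundle.wraps and wrapped:
                        prim = bundle.wraps[0]
                        apply(prim.body, -f * ta, a_w)
                        apply(prim.body, -f * tb, b_w)
                if detail:
                    info["ligament"][cab.name] = {"l": float(length), "eps": float(eps),
                                                  "elastic": float(f)}
                continue

            if cab.kind == "tension" and cab.wraps:
                # muscle riding a bony pulley (e.g. the triceps over the
                # olecranon/trochlea): constant tension along a wrapped path
                prim = cab.wraps[0]
                pw, Rw = poses[prim.body]
                a_l = Rw.T @ (a_w - pw)
                b_l = Rw.T @ (b_w - pw)
                length, ta_l, tb_l, wrapped = wrap_route(a_l, b_l, cab.wraps,
                                                         strict=False)
                ta, tb = Rw @ ta_l, Rw @ tb_l
                V += cab.tension * length
                apply(cab.a_body, cab.tension * ta, a_w)
                apply(cab.b_body, cab.tension * tb, b_w)
                if wrapped:
                    apply(prim.body, -cab.tension * ta, a_w)
                    apply(prim.body, -cab.tension * tb, b_w)
                continue

            d = b_w - a_w
            length = math.sqrt(float(d @ d))
            u = d / length if length > 1e-12 else np.zeros(3)
            if cab.kind == "tension":
                V += cab.tension * length
                f = cab.tension
            elif cab.kind == "linear":
                stretch = length - cab.rest
                V += 0.5 * cab.k * stretch * stretch
                f = cab.k * stretch
            else:
                raise ValueError(f"unknown cable kind {cab.kind!r}")
            if f != 0.0:
                apply(cab.a_body, f * u, a_w)
                apply(cab.b_body, -f * u, b_w)

        # relative-rotation springs (isotropic; the reaction axis maps
        # through the reference relative rotation)
        for spr in self.rot_springs:
            Ra = poses[spr.body_a][1]
            Rb = poses[spr.body_b][1]
            rv = _rotvec_from_matrix(Ra @ Rb.T @ spr.R_rel0.T)
            V += 0.5 * spr.k * float(rv @ rv)
            torques[spr.body_a] += -spr.k * rv
            torques[spr.body_b] += spr.k * (spr.R_rel0.T @ rv)

        # bushings
        for bsh in self.bushings:
            p, R = poses[bsh.body]
            dp = p - bsh.p_ref
            V += 0.5 * float(np.sum(bsh.k_t * dp * dp))
            apply(bsh.body, -bsh.k_t * dp, p)
            rv = _rotvec_from_matrix(R @ bsh.R_ref.T)
            V += 0.5 * float(np.sum(bsh.k_r * rv * rv))
            torques[bsh.body] += -bsh.k_r * rv

        # assemble gradient over free coordinates
        g = np.zeros(self.ndof)
        for name in self.free:
            i = self.index[name]
            th = q[6 * i + 3: 6 * i + 6]
            g[6 * i: 6 * i + 3] = -forces[name]
            g[6 * i + 3: 6 * i + 6] = -_left_jacobian(th).T @ torques[name]

        if detail:
            info["forces"] = forces
            info["torques"] = torques
            return V, g, info
        return V, g


# --------------------------------------------------------------------------
# system assembly
# --------------------------------------------------------------------------

def _rx(theta):
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def reference_poses(geometry: ElbowGeometry) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Nested reference poses of all bodies at the initial flexion angle."""
    cfg = geometry.config
    th = math.radians(cfg.initial_flexion)
    R = _rx(th)
    cap = np.array([cfg.capitellum_offset, 0.0, 0.0])
    d_distal = R @ np.array([0.0, 0.0, -1.0])
    p_radius = cap + (cfg.capitellum_radius + cfg.notch_clearance) * d_distal
    wrist_local = geometry.landmarks["radius"]["wrist_center"]
    p_hand = p_radius + R @ wrist_local
    return {
        "humerus": (np.zeros(3), np.eye(3)),
        "ulna": (np.zeros(3), R.copy()),
        "radius": (p_radius, R.copy()),
        "hand": (p_hand, np.eye(3)),
    }


def assemble_system(
    geometry: ElbowGeometry,
    bundles: dict[str, LigamentBundle],
    joints: list[JointConstraint] | None = None,
    loads: ExternalLoad | None = None,
    contact_uh: ContactParameters | None = None,
    contact_rh: ContactParameters | None = None,
) -> EnergyModel:
    """Build the elbow energy model from geometry, atlas and rig description.

    Per-element contact stiffness scales with element area relative to the
    nominal 5 x 5 mm element the configured ``kc`` values refer to.
    """
    joints = default_joints() if joints is None else joints
    loads = ExternalLoad() if loads is None else loads
    loads.validate()
    contact_uh = _contact.ULNOHUMERAL if contact_uh is None else contact_uh
    contact_rh = _contact.RADIOHUMERAL if contact_rh is None else contact_rh
    contact_uh.validate()
    contact_rh.validate()
    cfg = geometry.config

    refs = reference_poses(geometry)
    g_mm = 9.81  # kg -> N
    bodies = {}
    for name in ("humerus", "ulna", "radius", "hand"):
        mass = loads.masses.get(name, 0.0)
        bodies[name] = Body(
            name=name,
            prescribed=(name == "humerus"),
            p_ref=refs[name][0].copy(),
            R_ref=refs[name][1].copy(),
            weight=mass * g_mm if loads.gravity else 0.0,
            com_local=np.asarray(loads.com_local.get(name, (0, 0, 0)), dtype=float),
        )

    known = {"humerus", "ulna", "radius", "hand", "ground"}
    for name, att in geometry.attachments.items():
        for b in (att.origin_body, att.insertion_body):
            if b not in known:
                raise ValueError(f"attachment {name!r} references unknown body {b!r}")

    model = EnergyModel(bodies)
    model.gravity = loads.gravity

    # contact: trochlear elements vs the sigmoid notch, capitellar elements
    # vs the radial head dish
    nominal_area = cfg.element_edge**2
    for region, patch_body, patch, params in (
        ("trochlea", "ulna", NotchSurface(cfg), contact_uh),
        ("capitellum", "radius", DishSurface(cfg), contact_rh),
    ):
        els = geometry.elements_in(region)
        model.contacts.append(
            _ContactGroup(
                element_body="humerus",
                patch_body=patch_body,
                patch=patch,
                centers_local=np.stack([e.center for e in els]),
                areas=np.array([e.area for e in els]),
                kc=np.array([params.kc * e.area / nominal_area for e in els]),
                params=params,
                region=region,
            )
        )

    # ligaments
    for name, bundle in bundles.items():
        model.cables.append(
            _Cable(
                kind="ligament",
                a_body=bundle.origin_body, a_local=bundle.origin,
                b_body=bundle.insertion_body, b_local=bundle.insertion,
                bundle=bundle, name=name,
            )
        )

    # muscles (constant tensions, straight lines of action)
    hum, uln = geometry.landmarks["humerus"], geometry.landmarks["ulna"]
    if loads.triceps > 0:
        # the triceps rides the posterior trochlea/olecranon pulley, which
        # preserves its extension moment and the joint compression it
        # supplies through deep flexion
        from .geometry import WrapPrimitive

        pulley = WrapPrimitive(
            kind="cylinder", body="humerus", point=(0.0, 0.0, 0.0),
            radius=cfg.trochlea_radius + 1.5, axis=(1.0, 0.0, 0.0),
        )
        model.cables.append(_Cable(
            kind="tension", a_body="humerus", a_local=hum["triceps_origin"],
            b_body="ulna", b_local=uln["olecranon_tip"],
            tension=loads.triceps, name="triceps", wraps=(pulley,),
        ))
    if loads.brachialis > 0:
        model.cables.append(_Cable(
            kind="tension", a_body="humerus", a_local=hum["brachialis_origin"],
            b_body="ulna", b_local=uln["coronoid_tip"],
            tension=loads.brachialis, name="brachialis",
        ))

    # radio-ulnar tethers: a distal-joint surrogate at the styloids plus the
    # interosseous membrane represented as single force elements.  Together
    # with the annular wrap they hold the forearm in the fixed full-pronated
    # posture (the membrane elements are what resists relative long-axis
    # spin of the radius, which contact and the annular wrap cannot see).
    def tether(name, ulna_lm, radius_lm, k):
        a_local = geometry.landmarks["ulna"][ulna_lm]
        b_local = geometry.landmarks["radius"][radius_lm]
        a_w = refs["ulna"][0] + refs["ulna"][1] @ a_local
        b_w = refs["radius"][0] + refs["radius"][1] @ b_local
        model.cables.append(_Cable(
            kind="linear", a_body="ulna", a_local=a_local,
            b_body="radius", b_local=b_local,
            k=k, rest=float(np.linalg.norm(b_w - a_w)), name=name,
        ))

    tether("distal_radioulnar", "ulna_styloid", "radial_styloid", 35.0)
    if loads.interosseous:
        tether("io_membrane_proximal", "io_proximal", "io_proximal", 8.0)
        tether("io_membrane_distal", "io_distal", "io_distal", 8.0)

    # joints
    for joint in joints:
        if joint.type == "translational":
            continue  # realised by prescribing the humerus pose
        if joint.type == "spherical":
            model.cables.append(_Cable(
                kind="linear",
                a_body="radius", a_local=geometry.landmarks["radius"]["wrist_center"],
                b_body="hand", b_local=np.zeros(3),
                k=joint.penalty, rest=0.0, name="wrist",
            ))
            if joint.rot_penalty > 0:
                # the carpus transmits long-axis (pronation) torque between
                # the radius and the plate-strapped hand
                model.rot_springs.append(_RelRotSpring(
                    body_a="radius", body_b="hand",
                    R_rel0=refs["radius"][1] @ refs["hand"][1].T,
                    k=joint.rot_penalty,
                ))
        elif joint.type == "bushing6dof":
            ks = joint.stiffness or (0.05, 0.05, 4.0, 200.0, 200.0, 200.0)
            model.bushings.append(_Bushing(
                body=joint.child,
                p_ref=refs[joint.child][0].copy(),
                R_ref=refs[joint.child][1].copy(),
                k_t=np.asarray(ks[:3], dtype=float),
                k_r=np.asarray(ks[3:], dtype=float),
            ))
        elif joint.type == "fixed":
            continue
        else:
            raise ValueError(f"unknown joint type {joint.type!r}")

    return model


# --------------------------------------------------------------------------
# static solve
# --------------------------------------------------------------------------

def solve_static(model: EnergyModel, gtol: float = 1e-3, maxiter: int = 120):
    """Minimise the total potential from the current reference poses.

    Damped Newton (Levenberg-Marquardt) with the Hessian taken by central
    finite differences of the analytic gradient and a diagonal trust
    scaling, iterated until the generalized-force residual max-norm drops
    below ``gtol``.  The landscape mixes very stiff articular contact with
    very soft stabiliser springs (conditioning ~1e7), which plain
    first-order descent cannot traverse; the scaled damping keeps steps
    meaningful in both regimes.  Returns ``(q, residual, n_iter)``.
    """
    q = np.zeros(model.ndof)
    V, g = model.energy(q)
    it = 0
    for cycle in range(3):
        lam = 1e-3
        stalled = False
        H = None
        h_age = 99
        for _ in range(maxiter):
            it += 1
            if np.max(np.abs(g)) <= gtol:
                return q, float(np.max(np.abs(g))), it
            # the Hessian is reused over a few accepted steps; contact-set
            # changes make it stale quickly, so the age cap stays small
            if h_age >= 3:
                H = _fd_hessian(model, q, g0=g)
                h_age = 0
            D = np.diag(np.maximum(np.abs(np.diag(H)), 1e-3))
            accepted = False
            for attempt in range(35):
                try:
                    dq = np.linalg.solve(H + lam * D, -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                # trust cap: never move more than a few mm / hundredths of a
                # radian in one Newton step, so the solver tracks the local
                # equilibrium branch instead of hopping basins
                caps = []
                for i in range(0, len(q), 6):
                    mp = np.max(np.abs(dq[i:i + 3]))
                    mr = np.max(np.abs(dq[i + 3:i + 6]))
                    if mp > 3.0:
                        caps.append(3.0 / mp)
                    if mr > 0.08:
                        caps.append(0.08 / mr)
                if caps:
                    dq = dq * min(caps)
                Vn, gn = model.energy(q + dq)
                if np.isfinite(Vn) and (Vn < V or np.max(np.abs(gn)) < 0.9 * np.max(np.abs(g))):
                    q = q + dq
                    V, g = Vn, gn
                    lam = max(lam * 0.3, 1e-9)
                    accepted = True
                    h_age += 1
                    break
                if h_age > 0:
                    # the reused Hessian may be stale; refresh before damping up
                    H = _fd_hessian(model, q, g0=g)
                    h_age = 0
                    D = np.diag(np.maximum(np.abs(np.diag(H)), 1e-3))
                    continue
                lam *= 10.0
            if not accepted:
                stalled = True
                break
        if not stalled:
            break
        # stalls happen at snap-through saddles: kick along the direction of
        # most negative curvature (downhill side), then resume Newton; if the
        # curvature is all positive, fall back to a first-order restart
        H = _fd_hessian(model, q)
        w, vecs = np.linalg.eigh(H)
        moved = False
        if w[0] < 0.0:
            v = vecs[:, 0]
            for step in (0.05, 0.01, 0.002):
                for sign in (1.0, -1.0):
                    Vn, gn = model.energy(q + sign * step * v)
                    if Vn < V:
                        q = q + sign * step * v
                        V, g = Vn, gn
                        moved = True
                        break
                if moved:
                    break
        if not moved:
            res = minimize(model.energy, q, jac=True, method="L-BFGS-B",
                           options={"maxiter": 200, "ftol": 1e-16, "gtol": 1e-10})
            it += int(res.nit)
            if res.fun < V or np.max(np.abs(res.jac)) < np.max(np.abs(g)):
                q = res.x
                V, g = model.energy(q)
    return q, float(np.max(np.abs(g))), it


def _relax(model: EnergyModel, gtol: float, drive_update=None) -> np.ndarray:
    """Overdamped first-order relaxation from the current reference state.

    Integrates ``mu q_dot = -grad V`` with stiff implicit (BDF) stepping;
    used to traverse snap-through instabilities where no statically
    trackable equilibrium branch connects consecutive drive steps.  When
    ``drive_update(s)`` is given (``s`` in [0, 1]), the prescribed drive is
    ramped during the first stage so the flow follows the physical
    quasistatic path through the fold instead of jumping basins.
    """
    from scipy.integrate import solve_ivp

    mu = np.tile(np.concatenate([np.full(3, 0.5), np.full(3, 50.0)]),
                 len(model.free))
    q = np.zeros(model.ndof)
    ramp_time = 25.0

    def rhs(t, y):
        if drive_update is not None:
            drive_update(min(t / ramp_time, 1.0))
        return -model.energy(y)[1] / mu

    for stage in range(8):
        sol = solve_ivp(rhs, (0.0 if stage == 0 else ramp_time,
                              ramp_time * (stage + 1)),
                        q, method="BDF", rtol=1e-5, atol=1e-7)
        q = sol.y[:, -1]
        if drive_update is not None:
            drive_update(1.0)
        _, g = model.energy(q)
        if np.max(np.abs(g)) < 10.0 * gtol:
            break
    return q


def _fd_hessian(model: EnergyModel, q: np.ndarray, h: float = 1e-6,
                g0: np.ndarray | None = None) -> np.ndarray:
    """Finite-difference Hessian of the energy (forward differences when the
    base gradient is supplied, central otherwise)."""
    n = len(q)
    H = np.zeros((n, n))
    if g0 is not None:
        for j in range(n):
            qp = q.copy(); qp[j] += h
            _, gp = model.energy(qp)
            H[:, j] = (gp - g0) / h
    else:
        for j in range(n):
            qp = q.copy(); qp[j] += h
            qm = q.copy(); qm[j] -= h
            _, gp = model.energy(qp)
            _, gm = model.energy(qm)
            H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


# --------------------------------------------------------------------------
# flexion run
# --------------------------------------------------------------------------

def _ulna_flexion(geometry: ElbowGeometry, poses) -> float:
    frames = {}
    for body in ("humerus", "ulna"):
        p, R = poses[body]
        world = {k: p + R @ v for k, v in geometry.landmarks[body].items()}
        frames[body] = frame_from_landmarks(body, world)
    return decompose_jcs(frames["humerus"], frames["ulna"]).flexion


def run_flexion_sim(
    model: EnergyModel,
    geometry: ElbowGeometry,
    drive: MotionDrive | None = None,
    config: SimulationConfig | None = None,
) -> SimulationTrace:
    """Advance the prescribed humeral-head displacement and record the trace.

    Quasistatic continuation with warm starts and adaptive step halving at
    non-converged steps; terminates at full displacement or when the ulna
    flexion angle passes ``config.max_flexion``.  Joint separation beyond
    ``config.separation_bound`` raises the dislocation-candidate flag but
    the run continues (complete dislocation is a reportable outcome, not
    an error).
    """
    drive = MotionDrive() if drive is None else drive
    config = SimulationConfig() if config is None else config
    config.validate()

    bodies = model.bodies
    hum0 = bodies["humerus"].p_ref.copy()
    direction = np.asarray(drive.direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    times = np.linspace(0.0, drive.duration, config.n_steps + 1)
    rec: dict[str, list] = {name: [] for name in bodies}
    rec_R: dict[str, list] = {name: [] for name in bodies}
    lig_names = [c.name for c in model.cables if c.kind == "ligament"]
    lig_rec = {n: {"l": [], "eps": [], "elastic": []} for n in lig_names}
    regions = [g.region for g in model.contacts]
    con_rec = {r: {"delta": [], "elastic": []} for r in regions}
    t_rec, d_rec, flex_rec, res_rec, it_rec = [], [], [], [], []

    def record(t, d, q):
        poses = model.poses(q)
        V, g, info = model.energy(q, detail=True)
        for name in bodies:
            p, R = poses[name]
            rec[name].append(p.copy())
            rec_R[name].append(R.copy())
        for n in lig_names:
            st = info["ligament"][n]
            lig_rec[n]["l"].append(st["l"])
            lig_rec[n]["eps"].append(st["eps"])
            lig_rec[n]["elastic"].append(st["elastic"])
        for r in regions:
            con_rec[r]["delta"].append(info["contact"][r]["delta"])
            con_rec[r]["elastic"].append(info["contact"][r]["elastic"])
        t_rec.append(t)
        d_rec.append(d)
        flex_rec.append(_ulna_flexion(geometry, poses))

    # settle at zero displacement
    q, residual, iters = solve_static(model, gtol=config.gtol)
    model.recenter(q)
    record(times[0], 0.0, np.zeros(model.ndof))
    res_rec.append(residual)
    it_rec.append(iters)

    prev_d = 0.0
    if config.solver == "dynamic":
        from scipy.integrate import solve_ivp

    for k in range(1, len(times)):
        t = times[k]
        target = float(drive.displacement(t))
        # adaptive sub-stepping toward the target displacement
        lo = prev_d
        pending = [target]
        halvings = 0
        while pending:
            d = pending[-1]
            bodies["humerus"].p_ref = hum0 + d * direction
            if config.solver == "quasistatic":
                q, residual, iters = solve_static(model, gtol=config.gtol)
                ok = residual <= 10.0 * config.gtol
                # continuation guard: an equilibrium far from the warm start
                # usually means the minimiser hopped basins; refine the drive
                # step instead (a genuine snap survives refinement and is
                # accepted at the halving floor)
                if ok and halvings < config.max_step_halvings:
                    dq_pos = max(
                        float(np.max(np.abs(q[6 * i: 6 * i + 3])))
                        for i in range(len(model.free))
                    )
                    dq_rot = max(
                        float(np.max(np.abs(q[6 * i + 3: 6 * i + 6])))
                        for i in range(len(model.free))
                    )
                    if dq_pos > 6.0 or dq_rot > 0.15:
                        ok = False
            else:
                mu = np.tile(np.concatenate([np.full(3, 1.0), np.full(3, 200.0)]),
                             len(model.free))
                sol = solve_ivp(
                    lambda _t, y: -model.energy(y)[1] / mu,
                    (0.0, 50.0), np.zeros(model.ndof), method="BDF",
                    rtol=1e-6, atol=1e-8,
                )
                q = sol.y[:, -1]
                _, gfin = model.energy(q)
                residual, iters = float(np.max(np.abs(gfin))), int(sol.nfev)
                ok = sol.success
            if not ok and config.solver == "quasistatic" and \
                    halvings >= config.max_step_halvings:
                # snap-through: no statically trackable branch at the finest
                # drive refinement.  Let the dampers act: integrate the
                # overdamped dynamics while ramping the drive through the
                # fold, then polish statically.
                log.info("relaxing through snap at drive %.2f mm (step %d)", d, k)

                def drive_update(s, _lo=lo, _d=d):
                    bodies["humerus"].p_ref = hum0 + (_lo + s * (_d - _lo)) * direction

                drive_update(0.0)
                # alternate damped-flow relaxation and static polish: the
                # flow can park on a saddle's stable manifold, from which
                # one more relaxation round (after the polish nudges off
                # it) reaches the far basin
                for attempt in range(3):
                    q = _relax(model, config.gtol,
                               drive_update=drive_update if attempt == 0 else None)
                    model.recenter(q)
                    q, residual, iters = solve_static(model, gtol=config.gtol)
                    # through a snap the polished residual may sit above
                    # the regular-step tolerance; a fraction of a Newton
                    # against tens-of-Newton joint loads is accepted
                    if residual <= max(10.0 * config.gtol, 0.1):
                        break
                    model.recenter(q)
                ok = residual <= max(10.0 * config.gtol, 0.1)
            if ok:
                model.recenter(q)
                pending.pop()
                lo = d
            else:
                halvings += 1
                if halvings > config.max_step_halvings:
                    raise RuntimeError(
                        f"solver failed at drive displacement {d:.3f} mm "
                        f"(step {k}, residual {residual:.3g})"
                    )
                pending.append(0.5 * (lo + d))
        prev_d = target
        record(t, target, np.zeros(model.ndof))
        res_rec.append(residual)
        it_rec.append(iters)
        if flex_rec[-1] >= config.max_flexion:
            log.info("terminating at flexion %.1f deg (step %d)", flex_rec[-1], k)
            break

    trace = SimulationTrace(
        times=np.array(t_rec),
        drive=np.array(d_rec),
        flexion=np.array(flex_rec),
        positions={n: np.stack(v) for n, v in rec.items()},
        rotations={n: np.stack(v) for n, v in rec_R.items()},
        ligament={
            n: {k2: np.array(v2) for k2, v2 in d2.items()} for n, d2 in lig_rec.items()
        },
        contact_delta={r: np.stack(con_rec[r]["delta"]) for r in regions},
        contact_force={r: np.stack(con_rec[r]["elastic"]) for r in regions},
        element_area={
            g.region: g.areas.copy() for g in model.contacts
        },
        element_uv={
            g.region: np.array([
                e.map_uv for e in geometry.elements_in(g.region)
            ]) for g in model.contacts
        },
        residuals=np.array(res_rec),
        iterations=np.array(it_rec),
    )

    _finalize_rates(trace, model, geometry)
    trace.validate()
    return trace


def _finalize_rates(trace: SimulationTrace, model: EnergyModel, geometry: ElbowGeometry):
    """Add damper contributions from finite-difference rates; flag separation."""
    dt = np.diff(trace.times)
    # ligament total force = elastic + parallel damper, clamped at zero
    bundles = {c.name: c.bundle for c in model.cables if c.kind == "ligament"}
    for name, arrs in trace.ligament.items():
        l = arrs["l"]
        l_dot = np.concatenate([[0.0], np.diff(l) / dt])
        b = bundles[name]
        total = arrs["elastic"] + (b.c * l_dot if b.active else 0.0)
        arrs["l_dot"] = l_dot
        arrs["force"] = np.where(
            (arrs["elastic"] > 0) | (arrs["eps"] > 0), np.maximum(total, 0.0), 0.0
        ) if b.active else np.zeros_like(l)

    # contact total force = elastic + smoothed damping * penetration rate
    groups = {g.region: g for g in model.contacts}
    for region, delta in trace.contact_delta.items():
        grp = groups[region]
        ddot = np.vstack([np.zeros((1, delta.shape[1])), np.diff(delta, axis=0) / dt[:, None]])
        nominal = grp.params
        fc = np.zeros_like(delta)
        scale = grp.kc / nominal.kc
        for j in range(delta.shape[1]):
            pj = ContactParameters(kc=grp.kc[j], n=nominal.n,
                                   Bmax=nominal.Bmax * scale[j], dmax=nominal.dmax)
            fc[:, j] = _contact.contact_normal_force(delta[:, j], ddot[:, j], pj)
        trace.contact_force[region] = fc

    # dislocation candidate: one compartment completely out of contact over
    # a contiguous flexion span wider than 10 degrees (congruent contact
    # legitimately concentrates on a few elements, so partial unloading is
    # normal articulation, not dislocation)
    flex = trace.flexion
    for region, delta in trace.contact_delta.items():
        frac_lost = np.mean(delta <= 0.0, axis=1)
        lost = frac_lost >= 1.0
        span = 0.0
        start = None
        for i in range(len(lost)):
            if lost[i] and start is None:
                start = flex[i]
            elif not lost[i] and start is not None:
                span = max(span, flex[i - 1] - start)
                start = None
        if start is not None:
            span = max(span, flex[-1] - start)
        if span > 10.0:
            trace.dislocation_candidate = True
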