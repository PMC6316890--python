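"""Joint-coordinate-system kinematics.

Anatomical body frames follow the package-wide convention (+x lateral
flexion axis, +y anterior, +z proximal, right arm).  The relative rotation
of a distal bone (ulna or radius) with respect to the humerus is
decomposed on the clinical floating-axis sequence: a body-fixed flexion
axis on the humerus (e1 = humeral x), a body-fixed long axis on the distal
bone (e3 = distal z) and the mutually perpendicular floating axis (e2).
This is equivalent to an intrinsic X-Y-Z Euler factorisation of the
relative rotation, with gimbal proximity when varus-valgus approaches
90 degrees (far outside the physiological range of the elbow).

Sign conventions of the reported degrees of freedom (right arm):

* F-E   — flexion positive,
* VR-VL — valgus positive,
* I-E   — internal rotation positive,
* M-L   — medial translation positive,
* A-P   — anterior translation positive,
* S-I   — superior (proximal) translation positive.

Translations are the components of the humerus-origin-to-distal-origin
vector on the (e1, e2, e3) triad.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "BodyFrame",
    "JCSSample",
    "frame_from_landmarks",
    "decompose_jcs",
    "compose_jcs",
    "resample_by_flexion",
    "difference_vs_intact",
    "DOF_NAMES",
]

DOF_NAMES = ("F-E", "VR-VL", "I-E", "M-L", "A-P", "S-I")


@dataclass
class BodyFrame:
    """Anatomical frame of one bone: origin plus right-handed axes (rows)."""

    body: str
    origin: np.ndarray          # 3, world mm
    axes: np.ndarray            # 3x3, rows = x (flexion/lateral), y, z (long/proximal)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        R = self.axes
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError(f"frame axes of {self.body!r} are not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError(f"frame axes of {self.body!r} are left-handed")

    @property
    def rotation(self) -> np.ndarray:
        """World-from-frame rotation matrix (columns = frame axes in world)."""
        return self.axes.T


@dataclass
class JCSSample:
    """One clinical six-degree-of-freedom sample (angles deg, translations mm)."""

    body: str
    flexion: float
    varus_valgus: float         # valgus positive
    internal_external: float    # internal positive
    medial_lateral: float       # medial positive
    anterior_posterior: float   # anterior positive
    superior_inferior: float    # superior positive

    def as_array(self) -> np.ndarray:
        return np.array([
            self.flexion, self.varus_valgus, self.internal_external,
            self.medial_lateral, self.anterior_posterior, self.superior_inferior,
        ])


def _orthonormalize(x, z):
    """Right-handed frame rows from an approximate x and exact z."""
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    y = y / np.linalg.norm(y)
    x = np.cross(y, z)
    return np.stack([x, y, z])


def frame_from_landmarks(body: str, world_landmarks: dict[str, np.ndarray]) -> BodyFrame:
    """Deterministic anatomical frame from digitised landmarks.

    Humerus: origin at the trochlea centre, long axis toward the humeral
    head, flexion axis along the epicondylar line (medial -> lateral).
    Ulna: origin at the notch centre, long axis styloid -> notch
    (pointing proximal), anterior reference from the coronoid tip.
    Radius: origin at the radial head centre, long axis styloid -> head.
    """
    lm = {k: np.asarray(v, float) for k, v in world_landmarks.items()}
    if body == "humerus":
        origin = lm["trochlea_center"]
        z = lm["humeral_head"] - origin
        x = lm["lateral_epicondyle"] - lm["medial_epicondyle"]
        return BodyFrame(body, origin, _orthonormalize(x, z))
    if body == "ulna":
        origin = lm["notch_center"]
        z = origin - lm["ulna_styloid"]
        y_ref = lm["coronoid_tip"] - lm["olecranon_tip"]
        x = np.cross(y_ref, z)
        return BodyFrame(body, origin, _orthonormalize(x, z))
    if body == "radius":
        origin = lm["radial_head_center"]
        z = origin - lm["radial_styloid"]
        x = lm["head_rim_lateral"] - origin
        return BodyFrame(body, origin, _orthonormalize(x, z))
    raise ValueError(f"no frame recipe for body {body!r}")


def decompose_jcs(frame_humerus: BodyFrame, frame_distal: BodyFrame) -> JCSSample:
    """Decompose a relative pose into the six clinical degrees of freedom."""
    R_rel = frame_humerus.axes @ frame_distal.rotation   # distal frame in humerus coords
    alpha, beta, gamma = Rotation.from_matrix(R_rel).as_euler("XYZ")
    if abs(abs(np.degrees(beta)) - 90.0) < 5.0:
        warnings.warn(
            "varus-valgus near 90 degrees: joint coordinate system is close "
            "to gimbal lock; angles are still returned",
            RuntimeWarning,
            stacklevel=2,
        )

    t_world = frame_distal.origin - frame_humerus.origin
    e1 = frame_humerus.axes[0]            # humeral flexion axis (lateral +)
    e3 = frame_distal.axes[2]             # distal long axis (proximal +)
    e2 = np.cross(e3, e1)
    n2 = np.linalg.norm(e2)
    e2 = e2 / n2 if n2 > 1e-12 else frame_humerus.axes[1]

    return JCSSample(
        body=frame_distal.body,
        flexion=float(np.degrees(alpha)),
        varus_valgus=float(-np.degrees(beta)),       # valgus positive
        internal_external=float(np.degrees(gamma)),  # internal positive
        medial_lateral=float(-(t_world @ e1)),       # medial positive
        anterior_posterior=float(t_world @ e2),
        superior_inferior=float(t_world @ e3),
    )


def compose_jcs(sample: JCSSample, frame_humerus: BodyFrame) -> BodyFrame:
    """Rebuild the distal frame from a JCS sample (inverse of decompose)."""
    alpha = np.radians(sample.flexion)
    beta = -np.radians(sample.varus_valgus)
    gamma = np.radians(sample.internal_external)
    R_rel = Rotation.from_euler("XYZ", [alpha, beta, gamma]).as_matrix()
    axes = (frame_humerus.axes.T @ R_rel).T

    e1 = frame_humerus.axes[0]
    e3 = axes[2]
    e2 = np.cross(e3, e1)
    n2 = np.linalg.norm(e2)
    e2 = e2 / n2 if n2 > 1e-12 else frame_humerus.axes[1]
    # the JCS triad is not orthogonal (e1 . e3 != 0 away from neutral);
    # the decomposition stores covariant components t . e_i, so recover t
    # through the dual basis, i.e. solve E t = components
    E = np.stack([e1, e2, e3])
    comps = np.array([
        -sample.medial_lateral,
        sample.anterior_posterior,
        sample.superior_inferior,
    ])
    t = np.linalg.solve(E, comps)
    return BodyFrame(sample.body, frame_humerus.origin + t, axes)


# --------------------------------------------------------------------------
# flexion-grid resampling and comparison
# --------------------------------------------------------------------------

def _monotone_segment(flexion: np.ndarray) -> np.ndarray:
    """Indices of the strictly increasing envelope of the flexion record."""
    keep = [0]
    best = flexion[0]
    for i in range(1, len(flexion)):
        if flexion[i] > best:
            keep.append(i)
            best = flexion[i]
    return np.asarray(keep)


def resample_by_flexion(samples: list[JCSSample], start: float, stop: float,
                        step: float) -> list[JCSSample]:
    """Linear interpolation of each DOF on the half-open flexion grid.

    Grid points are ``start, start+step, ..., stop-step`` — the half-open
    convention ``[start, stop)`` yields ``(stop-start)/step`` samples (40
    for the standard 50-130 degree window at 2 degree spacing).  Only the
    monotone-flexion envelope of the trace is used.
    """
    if not samples:
        raise ValueError("empty sample list")
    flexion = np.array([s.flexion for s in samples])
    data = np.stack([s.as_array() for s in samples])
    idx = _monotone_segment(flexion)
    flexion = flexion[idx]
    data = data[idx]

    if flexion[0] > start + 1e-9 or flexion[-1] < stop - 1e-9:
        raise ValueError(
            f"trace covers flexion [{flexion[0]:.2f}, {flexion[-1]:.2f}] degrees, "
            f"cannot resample [{start}, {stop}]"
        )
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n)
    body = samples[0].body
    out = []
    for g in grid:
        row = np.array([np.interp(g, flexion, data[:, j]) for j in range(data.shape[1])])
        out.append(JCSSample(body, *row))
    return out


def difference_vs_intact(samples_condition: list[JCSSample],
                         samples_intact: list[JCSSample]):
    """Per-DOF (condition - intact) series with mean and sample SD.

    Both inputs must be on the same flexion grid.  Returns
    ``(diff, summary)`` where ``diff`` is an ``(n, 6)`` array in DOF order
    and ``summary`` maps DOF name -> ``(mean, sd)``.
    """
    if len(samples_condition) != len(samples_intact):
        raise ValueError("flexion grids differ in length")
    dc = np.stack([s.as_array() for s in samples_condition])
    di = np.stack([s.as_array() for s in samples_intact])
    diff = dc - di
    summary = {}
    for j, name in enumerate(DOF_NAMES):
        col = diff[:, j]
        sd = float(np.std(col, ddof=1)) if len(col) > 1 else 0.0
        summary[name] = (float(np.mean(col)), sd)
    return diff, summary
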