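# Methods

This note documents the models behind `elbowsim`, the choices made where
the design was genuinely open, and what the synthetic study can and
cannot show about real elbows.

## The rig and the solution strategy

The simulated protocol is a cadaver-style passive flexion test.  The
humerus is constrained to the vertical axis by a prismatic joint and its
head is displaced 345 mm downward over 40 s (smoothstep profile by
default); the hand rests on a plate through a soft six-degree-of-freedom
spring (0.05/0.05/4.0 N/mm translation, 200 N·mm/rad rotation); the
wrist is a spherical joint between the distal radius and the hand,
realised as a 300 N/mm point penalty plus a 400 N·mm/rad isotropic
torsion spring.  The torsion spring represents pronation-moment transfer
through the carpus: with a pure ball wrist the forearm could spin freely
about its long axis while the hand stayed put, which is neither
anatomical nor stable.  Constant 40 N triceps and 20 N brachialis
tensions act along atlas anchor lines; the triceps rides a cylindrical
pulley at the posterior trochlea so its extension moment and the joint
compression it supplies survive deep flexion (a straight line of action
degenerates there, passing through the joint centre).  Gravity acts on
anthropometric segment masses (forearm 1.1 kg split ulna/radius, hand
0.45 kg); the ulnar centre of mass sits medial-anterior of the long axis,
which is how the fixed fully-pronated posture loads this reduced model.
An interosseous membrane (two linear elements) and a distal radio-ulnar
tether keep the forearm bones in their pronated relationship; the
membrane is what resists relative long-axis spin of the radius, which
neither the annular wrap (rotationally symmetric) nor frictionless
contact can see.

The drive is slow, so the run is solved as **quasistatic continuation**:
at each of the (default 160) drive increments the total potential energy
— contact + ligament + muscle path length + gravity + bushing and
penalty springs — is minimised over the 18 unconstrained coordinates
(ulna, radius, hand; 3 translations + 3 rotation-vector components each,
re-centred every step).  Gradients are analytic throughout (verified to
~1e-7 against finite differences in the test suite); minimisation is
damped Newton (Levenberg-Marquardt with a diagonal trust scaling and a
3 mm / 0.08 rad per-step cap, the Hessian by finite differences of the
gradient and reused over a few accepted steps).  A step is accepted when
the generalized-force residual max-norm is below 1e-3 (N for
translations, N·mm for rotations).  The energy landscape mixes ~1e2 N/mm
articular stiffness with ~5e-2 N/mm stabiliser springs (conditioning
~1e7), which is why plain first-order descent is not used.

Passive flexion of a lax joint has genuine snap-throughs (subluxation
onsets, reseating events).  When no statically trackable equilibrium
connects two drive increments even after six halvings of the increment,
the solver integrates the overdamped first-order dynamics
(`mu q̇ = −∇V`, stiff BDF) while ramping the drive through the fold, then
polishes statically; such steps are accepted with residuals up to 0.1 N,
a fraction of a percent of the joint loads, and recorded in the trace
diagnostics.  Velocity-dependent terms — the penetration-ramped contact
damper and the 0.5 Ns/mm parallel ligament dampers — carry no load at
equilibrium; they are evaluated for reporting from finite-difference
rates between accepted steps, and they are the physical justification
for the relaxation fallback.  An explicit "dynamic" solver mode exposes
the same overdamped integration for whole-run fidelity checks.

## Contact

Humeral cartilage only is discretized (default 5 × 5 mm grid over the
trochlear spool and the capitellar cap, 64 elements); the ulnar notch and
radial dish act as smooth opposing surfaces.  Each element applies
`Fc = kc δ + Bc(δ) δ̇` along the local surface gradient, with per-element
kc scaled by element area relative to the nominal 25 mm².  The defaults
kc = 126 / 105 N/mm are adopted constants for the two articulations; the
elastic-foundation route (E = 0.7 MPa, ν = 0.495, h = 4 / 4.8 mm) is
implemented separately and yields ≈148 N/mm for the ulnohumeral values —
the two routes deliberately coexist without reconciliation, since the
adopted constants originate from prior contact-parameter calibration
rather than from the foundation formula.  Pressure is force over element
area; contact area is the loaded-element count times element area.

Degenerate-input behaviour: separation returns zero force (no adhesion;
the total is clamped at zero so a fast-withdrawing damper cannot pull);
the damping ramp is C1 at first touch and at saturation; penetration
fields of the analytic surfaces are C1 everywhere, including the flared
sector margins (raised-cosine groove, quadratic margin flares), because
the minimiser requires a continuously differentiable energy.

## Ligaments

Each bundle: quadratic-toe/linear elastic law about a zero-load length,
tension-only, with exact stored-energy antiderivative (the solver
minimises energy, so force and energy must match analytically).
Zero-load lengths are set from the generated geometry: the bundle path
length at the reference pose divided by (1 + per-complex reference
strain).  Per-bundle stiffnesses and reference strains are calibration
constants of the synthetic elbow (AB 500 N/strain at 0.09, PB 150 at
0.03, LUCL 250 at 0.02, RCL 150 at 0.02, annular 150 at 0.0); they are
chosen so the intact simulation tracks neutrally with physiological peak
loads and strains, and are documented as such, not as tissue data.  The
anterior band is deliberately the dominant restraint and the posterior
band a weaker, near-isometric secondary — the asymmetry that makes
isolated AB loss slightly more consequential than isolated PB loss.

Wrapping (LUCL and annular bundles, plus the triceps pulley) uses exact
single-obstacle geodesics around spheres and cylinders with closed-form
path lengths and endpoint tangents; the returned endpoint vectors are the
negative path-length gradients, so wrenches on origin, insertion and
obstacle bodies are energy-consistent, including in the regularised
regime where a trial configuration grazes the obstacle (there the
effective radius shrinks continuously and the radius-sensitivity
dL/dr = wrapped arc is folded into the endpoint vectors).

Sectioning deactivates exactly the bundles of the chosen complex(es) and
is idempotent; all four study conditions run under the bitwise identical
drive.

## The synthetic elbow

The generator is a pure function of its configuration (including the
seed): same inputs, bitwise identical geometry.  The articulation is
parametric:

* **Trochlea** — a spool of lip radius 12 mm with a C1 raised-cosine
  groove (depth 2.2 mm) whose floor runs *obliquely*: the groove centre
  drifts laterally with patch angle at a peak rate of 12 mm/rad,
  saturating over ±0.95 rad of the arc.  A lateral flange (the
  capitulotrochlear ridge, +3 mm beyond 8 mm lateral) bounds medial
  excursion of the mating ridge.
* **Sigmoid notch** — the congruent concave surface (clearance 0.05 mm)
  over a 185° sector, flaring open C1-quadratically past the coronoid
  and olecranon margins.
* **Radiocapitellar joint** — a 10 mm capitellar sphere nested in a
  congruent dish of 70° cap angle on the radial head.
* **Atlas** — fourteen bundles with origins and insertions on anatomical
  prominences (medial epicondyle, sublime tubercle, medial olecranon,
  lateral epicondyle, supinator crest, radial notch rims), with ±0.2 mm
  seeded digitisation scatter on soft-tissue points; bony frame
  landmarks stay exact so anatomical frames are reproducible.

The oblique groove course is the load-generating mechanism of the study:
as the pronated forearm is flexed, the congruent ridge must either
follow the groove laterally or load the medial restraints.  Intact, the
MCL holds the ulna within a millimetre of its track and carries a
growing load; with the whole MCL sectioned the joint follows the oblique
course, opens medially, and rides into combined internal rotation and
lateral translation — arrested by the lateral ligaments, the membrane
and the wrist torsion path rather than by bone, which is why no complete
dislocation occurs.  Obliquity magnitude, flange geometry, ligament
stiffnesses and the pronated mass offsets are the calibration set of the
synthetic elbow, fixed once so that the intact joint stays within the
stability envelope while complete MCL loss produces deep-flexion
internal rotation beyond 30° and lateral translation beyond 8 mm.  The
generator cannot, and does not claim to, reproduce subject-specific
magnitudes; printed per-specimen tables are out of reach without the
original geometries, and comparisons are therefore structural: orderings,
redistributions and contact-pattern changes.

A general mesh discretizer (area-weighted k-means tiling) handles
user-supplied STL/OBJ cartilage for the same element contract; the
parametric patches use exact grids with the analytic surface jacobian.

## Kinematics and statistics

Anatomical frames are built deterministically from landmarks (humeral
epicondylar line and shaft; ulnar styloid-to-notch long axis with the
coronoid fixing anterior; radial styloid-to-head axis).  The relative
rotation decomposes on the clinical floating-axis sequence — body-fixed
flexion axis on the humerus, body-fixed long axis on the distal bone,
floating axis between — equivalent to an intrinsic X-Y-Z Euler
factorisation; translations are covariant components on the (non-
orthogonal) JCS triad and are reconstructed through the dual basis, so
decompose/compose round-trips to 1e-9.  Signs follow the right-arm
clinical convention (internal, valgus, medial, anterior, superior
positive).  Gimbal proximity (|varus-valgus| near 90°) warns but still
returns values; the elbow never approaches it.

Traces are resampled by linear interpolation on the half-open flexion
grid [50°, 130°) at 2° — 40 samples per condition; the half-open
convention is a documented choice that makes the count come out at 40
rather than 41.  Only the strictly increasing envelope of the flexion
record is used, so post-peak artefacts cannot contaminate the grid.
Per-DOF one-way ANOVA over ligament state and Tukey-Kramer pairwise
comparisons versus intact (studentized-range distribution, Kramer
unequal-n correction) are computed from the classic formulas with
reference-implementation agreement enforced in the tests.  A caveat
carried over deliberately from the protocol: the 40 grid points of one
simulation are serially correlated, not independent specimens, so the
p-values describe sampled curves, not populations.

The dislocation-candidate flag marks a compartment completely out of
contact over a contiguous flexion span wider than 10°; partial unloading
of a congruent articulation concentrating load on a few elements is
normal articulation, not dislocation.

## Problem sizes and defaults

Default runs discretize the drive into 160 static solves (the study
pipeline and acceptance script use 110–120; results on the flexion grid
are insensitive to this between ~100 and 200 steps).  One condition
solves in a few minutes on one CPU; the four-condition study in roughly
a quarter hour.  All randomness (attachment scatter) flows from the
single geometry seed.

## Known limitations

* No joint capsule and only two muscle tensions: laxity under complete
  MCL loss is, if anything, exaggerated, as the protocol itself notes.
* Rigid cartilage with point-sampled elements: pressures are
  element-resolution quantities (checked only against the broad 0.5-5 MPa
  physiological range), not finite-element fields.
* The synthetic geometry reproduces constraint *structure*, not subject
  shape; per-specimen printed values are not reproducible targets.
* The quasistatic solver reports equilibria; transient dynamics during a
  snap-through (the speed of a subluxation event) is outside scope — only
  its endpoints are meaningful.
* Wrapping supports one engaged obstacle per cable, which covers every
  bundle in this model.
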