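# Methods

This note records the model conventions, numerical choices and known
limitations of `limbmoment`, and what the synthetic test geometry does
and does not establish about real limb models.

## Rigid-segment model and joint coordinate conventions

A limb model is a tree of rigid segments rooted at the trunk/pelvis.
Every segment frame coincides with the world frame at the neutral
posture, so attachment coordinates are neutral-posture world coordinates
tagged with the segment that carries them; this matches how gaitsym-style
model files record construction coordinates and makes the native dialect
human-checkable against a figure of the neutral pose.

Each joint stores a centre and a right-handed orthonormal triad in the
parent frame: Z is flexion–extension, X ab–adduction, Y long-axis
rotation.  Rotations compose intrinsically X(θ_aa) → Z(θ_fe) → Y(θ_la).
The composition order is a modelling convention, not a law: it was chosen
because the analyses sweep flexion–extension while holding ab–adduction
locked, which the X-before-Z order makes well defined (the flexion axis
at ab-adduction θ_aa is the Z axis rotated by Rx(θ_aa)); the
`euler_order` argument switches it if a model was built the other way
round.

Sign conventions are pinned to output semantics rather than to a global
handedness: each joint's triad is oriented so that a *positive* angle
flexes (hip: negative = extended; knee/ankle: 0 = fully extended,
increasing = flexed/dorsiflexed — the knee uses a mirrored triad for
this).  A muscle that lengthens during flexion is an extensor and gets a
positive moment arm by construction, with no post-hoc sign fixing.  The
units at every API surface are metres, kilograms and degrees; angles are
converted to radians only inside derivatives.

## Muscle paths, wrapping, and routed length

A strand is an ordered polyline of segment-bound points.  Consecutive
coincident points are dropped with a warning.  Cylindrical wrap
obstacles implement the standard obstacle-set construction: a path
segment whose closest 2D approach to the cylinder axis is below the
radius is replaced by straight tangent legs and a surface geodesic,
found in closed form by unrolling the cylinder (the routed path is a
straight line in the unrolled plane; tangent-point heights follow by
linear interpolation in unrolled arc length).  The `side` flag fixes the
wrap sense when anatomy dictates it; with no flag, ties break toward the
shorter route.  Endpoints strictly inside a cylinder are a degenerate
geometry and raise an error.  Engagement at exact tangency produces the
straight route, so routed length is continuous in pose across
engagement (verified to <10⁻⁶ m per 10⁻⁴ deg step).  Only cylinders are
supported; more general wrap shapes (ellipsoids, tori) are out of scope,
which matters at extreme joint angles where a cylinder is a poor stand-in
for condylar geometry — the demonstration model's gastrocnemius behaviour
past ~120° of knee flexion should be read with that caveat.

## Moment arms by two routes

*Tendon excursion*: MA = dL/dθ by central difference with a default step
of 0.1° (1.745·10⁻³ rad).  On desk-scale geometry the quadratic
truncation error of that step is far below the 10⁻⁶ m agreement target
for production sweeps; equivalence *measurements* against the geometric
method use a finer 0.002° probe so that the reported disagreement
reflects the methods, not the difference stencil (the truncation error
scales as h², verified by halving).  At a joint limit the difference
falls back to one-sided with a warning.  Strands whose bound segments
(points and wrap cylinders) all lie on one side of a joint return
exactly 0.0, not a rounded small number.

*Torque projection*: for every straight sub-segment of the routed path
with unit direction **u** and endpoints bound to segments, the endpoint
on the moving (distal) subtree contributes ±**â**·((**x**−**c**)×**u**).
Wrap tangent points are treated as material points of the cylinder's
segment; the surface geodesic connects two points of one rigid body, so
by the envelope property of the shortest route it drops out of the
derivative.  This makes the coaxial-cylinder pulley law (MA = radius,
to 10⁻⁹ m) exact rather than approximate.

Muscle-level moment arms are PCSA-fraction-weighted means of strand
moment arms; the weighting is the default and raw strand curves are
always exported alongside, so a reader preferring a representative
strand can take it from the same table.  Summed extensor/flexor curves
classify *strands* instantaneously at each grid angle with a ±10⁻⁶ m
dead band (a muscle may straddle the groups if its strands disagree);
muscle-level classification is available by summing the muscle curves
instead (`kind="muscle"`).

## Torque and architecture

τ = PCSA · MA · FPUA under maximal isometric contraction; no Hill-type
length or velocity dependence, no tendon elasticity, no activation
dynamics.  FPUA defaults to 300 000 N m⁻², the conventional mid-range
value (reported values span roughly 200 000–400 000 N m⁻²); it is a
single multiplicative constant, so every torque scales linearly with it.
PCSA is (mass/ρ)/FL with ρ = 1060 kg m⁻³ muscle density (configurable);
pennation is ignored, which for typical hind-limb pennation angles
(<30°) biases PCSA by at most ~13% (1−cos 30°).  Architecture tables may
carry PCSA directly; when mass and fascicle length are also present the
value is cross-checked and a >5% discrepancy warns.

Geometric-similarity scaling uses mass exponent 1 and length exponent
0.33 — literally 0.33, not 1/3, so PCSA scales with exponent 0.67; the
difference from the exact thirds is negligible but keeping the published
constant is free.  A `prescaled` flag on table reading marks tables
already referred to the model subject's mass, guarding against double
scaling.

## Sensitivity analysis

Attachment points are displaced in their segment frame on a deep copy of
the model; the perturbation is exactly local (all other muscles'
moment arms are bit-identical).  "Superior"/"inferior" map to ±Y of the
default frame — correct for models whose long axis is Y, overridable by
passing explicit vectors.  Reports give per-perturbation moment-arm
deltas, peak shifts and sign-change shifts against baseline.

## Locomotor ranges

Joint-angle intervals for bipedal walking, terrestrial quadrupedalism
and vertical climbing ship as an editable CSV in the model's angle
convention.  They are approximations: several sources publish only
graphs (values digitised by eye), climbing ankle dorsiflexion is known
only by its maximum (119°, stored as an open-ended interval that clips
to the sweep domain), and gorilla bipedal abduction angles are proxied
by chimpanzee values.  Range summaries use grid samples inside the
closed interval plus linearly interpolated endpoint values; mode
comparisons rank by mean |MA| and report ties explicitly.  No statistical
test is attached — the comparison is descriptive, as the underlying
kinematic samples are too sparse to support more.

## Synthetic geometry: what it shows and what it does not

The generators provide closed-form oracles: the coaxial-pulley hinge toy
(MA ≡ r while the wrap is engaged — engagement is guaranteed over ±50°
by placing the insertion at 1.2 r), the fan toy (strand moment arms are
the per-strand wrap radii, so the weighted-mean rule is testable
exactly), the tangent-line via toy (neutral MA = tangent height; the
radial-offset closed form c(r+d)/√(c²+d²) is first-order "MA grows by
d", with a 1.2 m tangent leg making the quadratic correction <10⁻⁶ m at
d = 5 mm), the two-joint toy (sign change at the planar collinearity
angle (φ_b − φ_a) mod 180°), and seeded random three-segment limbs with
randomly oriented joint triads for the cross-method property.

The demonstration hind limb is *synthetic*: gorilla-proportioned
(femur 27.1 cm, tibia 22.6 cm, 152 kg subject, 72 kg donor
architecture), with attachments chosen so the standard comparative
phenomenology emerges — hip extensor leverage peaking at −40…−20° and
falling with flexion, knee extensor dominance over 0–140°, gastrocnemius
origins just behind the knee producing a flexor→extensor switch near 90°
(delayed past 100° by a 1 cm superior origin shift), a rectus femoris
arising below a horizontally oriented pelvis that switches predicted
function at a flexed hip posture, and ankle plantarflexor leverage
peaking mid-dorsiflexion.  The foot segment's neutral coordinates
represent the fully plantarflexed posture, since ankle angle 0 means
fully extended.  Passing these checks shows the *pipeline* reproduces
the geometry it is given; it does not validate any particular animal's
anatomy, and no number from the demonstration model should be quoted as
a measurement of a real gorilla.

Problem sizes in the test suite and acceptance script (200 random
models, 2°–10° sweep grids, 10 pulley radii) were chosen as the smallest
sets that exercise every branch while keeping the full suite under a
minute of compute.

## Known limitations

* One wrap engagement per path segment (the first engaging cylinder
  wins); double wraps on a single segment are not routed.
* No translation at joints; joint centres are fixed in the parent
  segment.
* The gaitsym XML reader covers the subset needed here (bodies, hinge
  joints, muscle strap points, cylinder wraps, PCSA/fibre-length
  attributes) and is read-only; writing targets the native YAML dialect
  only.  Strand grouping by trailing-digit stripping is a heuristic and
  can be disabled.
* Moment arms are reported about the flexion–extension axis at locked
  ab–adduction/long-axis settings; ab–adduction and long-axis rotation
  are not swept degrees of freedom.
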