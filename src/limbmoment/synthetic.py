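"""Generators for synthetic limb models with analytically known answers.

Every pipeline stage is testable without any external model file:

* :func:`make_hinge_toy` -- a single hinge with a muscle wrapping a
  cylinder coaxial with the joint axis: the pulley geometry makes the
  moment arm exactly the cylinder radius while the wrap is engaged.
* :func:`make_fan_toy` -- a fan muscle whose strands wrap coaxial
  cylinders of different radii, so each strand's moment arm and the
  PCSA-weighted muscle moment arm have closed forms.
* :func:`make_via_tangent_toy` -- a via-point routing whose crossing
  segment runs tangent below the hinge axis; the moment arm equals the
  tangent height, and radial offsets of the insertion have a closed form.
* :func:`make_two_joint_toy` -- a muscle spanning two hinges with its
  origin close to the proximal one, reproducing the flexor-to-extensor
  switch of two-joint muscles at extreme flexion; the sign-change angle
  follows from planar trigonometry.
* :func:`make_random_model` -- seeded random three-segment limbs for
  property suites (cross-method moment-arm agreement etc.).
* :func:`make_demo_hindlimb` -- a synthetic gorilla-proportioned hind
  limb (trunk/thigh/shank/foot, ten muscles) used by the analysis
  scripts.  It is not derived from any specimen; attachments are chosen
  to reproduce the qualitative moment-arm phenomenology of ape hind
  limbs (hip extensor leverage falling with flexion, knee extensor
  dominance, distal two-joint muscles switching predicted function at
  extreme flexion).

Each generator attaches its closed-form expectations to
``model.annotations`` for use in tests.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    Joint,
    LimbModel,
    MuscleArchitecture,
    MusclePath,
    PathPoint,
    Segment,
    WrapCylinder,
)

__all__ = [
    "make_hinge_toy",
    "make_fan_toy",
    "make_via_tangent_toy",
    "make_two_joint_toy",
    "make_random_model",
    "make_demo_hindlimb",
]

#: Mirrored right-handed triad used for joints whose positive angle must
#: rotate the child the opposite way around world Z (knee convention:
#: zero = fully extended, increasing angle = more flexed).
_MIRRORED_TRIAD = np.array([[-1.0, 0.0, 0.0],
                            [0.0, 1.0, 0.0],
                            [0.0, 0.0, -1.0]]).T  # columns X, Y, Z


def _hinge_skeleton(limits_fe=(-80.0, 80.0)) -> tuple[dict, dict]:
    segments = {
        "proximal": Segment("proximal", None),
        "distal": Segment("distal", "proximal"),
    }
    joints = {
        "hinge": Joint(
            name="hinge",
            parent_segment="proximal",
            child_segment="distal",
            centre=np.zeros(3),
            axes=np.eye(3),
            limits_deg={"fe": limits_fe, "aa": (-30.0, 30.0), "la": (-30.0, 30.0)},
        )
    }
    return segments, joints


def make_hinge_toy(
    r_m: float, crossing: bool = True, pcsa_m2: float = 1e-4
) -> LimbModel:
    """Two segments, one Z-hinge, one muscle with closed-form moment arm.

    With ``crossing=True`` the muscle runs from the proximal segment over
    a wrap cylinder coaxial with the hinge (radius ``r_m``) to an
    insertion just outside the cylinder on the distal segment: the pulley
    property gives MA = +r exactly at every engaged angle (engagement
    documented over roughly +/-55 degrees; the sweeps used in tests stay
    within +/-50).  With ``crossing=False`` the muscle lies entirely on
    the proximal segment and MA = 0 identically.
    """
    if not r_m > 0:
        raise ValueError(f"wrap radius must be positive, got {r_m}")
    segments, joints = _hinge_skeleton()
    if crossing:
        paths = [
            MusclePath(
                muscle="pulley",
                strand="s1",
                points=[
                    PathPoint("proximal", (-0.25, 0.0, 0.0), "origin"),
                    PathPoint("distal", (1.2 * r_m, 0.0, 0.0), "insertion"),
                ],
                wraps=[
                    WrapCylinder(
                        segment="distal",
                        origin=(0.0, 0.0, 0.0),
                        direction=(0.0, 0.0, 1.0),
                        radius=r_m,
                        side=+1,  # route under the axis: MA = +r (extensor side)
                        label="coaxial pulley",
                    )
                ],
            )
        ]
        expected = r_m
    else:
        paths = [
            MusclePath(
                muscle="pulley",
                strand="s1",
                points=[
                    PathPoint("proximal", (-0.25, 0.0, 0.0), "origin"),
                    PathPoint("proximal", (-0.10, 0.05, 0.0), "insertion"),
                ],
            )
        ]
        expected = 0.0
    arch = {"pulley": MuscleArchitecture("pulley", pcsa_m2=pcsa_m2, donor_mass_kg=72.0)}
    return LimbModel(
        segments=segments,
        joints=joints,
        paths=paths,
        architecture=arch,
        body_mass_kg=72.0,
        bone_lengths_m={"femur": 0.271, "tibia": 0.226},
        name="hinge toy",
        annotations={
            "synthetic": True,
            "expected_ma_m": expected,
            "engaged_range_deg": (-50.0, 50.0) if crossing else None,
        },
    )


def make_fan_toy(n_strands: int, spread_m: float = 0.02, r0_m: float = 0.05) -> LimbModel:
    """Fan muscle: n strands from spread origins converge on one insertion.

    Strand ``k`` wraps a coaxial cylinder of radius ``r_k`` spanning
    ``[r0 - spread/2, r0 + spread/2]``, so strand moment arms are exactly
    ``r_k`` while engaged and the PCSA-fraction-weighted muscle moment arm
    is the weighted mean of the radii (for the default equal fractions and
    a symmetric spread this equals the middle strand's radius).
    """
    if n_strands < 1:
        raise ValueError(f"need at least one strand, got {n_strands}")
    if r0_m - spread_m / 2 <= 0:
        raise ValueError("spread too large: smallest wrap radius would be <= 0")
    segments, joints = _hinge_skeleton()
    if n_strands == 1:
        radii = [r0_m]
    else:
        radii = [
            r0_m + spread_m * (k / (n_strands - 1) - 0.5) for k in range(n_strands)
        ]
    r_max = max(radii)
    insertion = PathPoint("distal", (1.2 * r_max, 0.0, 0.0), "insertion")
    paths = []
    for k, r in enumerate(radii):
        paths.append(
            MusclePath(
                muscle="fan",
                strand=f"s{k + 1}",
                points=[
                    PathPoint("proximal", (-0.25 - 0.01 * k, 0.0, 0.0), "origin"),
                    insertion,
                ],
                wraps=[
                    WrapCylinder(
                        segment="distal",
                        origin=(0.0, 0.0, 0.0),
                        direction=(0.0, 0.0, 1.0),
                        radius=r,
                        side=+1,
                    )
                ],
                fraction=1.0 / n_strands,
            )
        )
    arch = {"fan": MuscleArchitecture("fan", mass_kg=0.4, fl_m=0.08, donor_mass_kg=72.0)}
    return LimbModel(
        segments=segments,
        joints=joints,
        paths=paths,
        architecture=arch,
        body_mass_kg=72.0,
        bone_lengths_m={"femur": 0.271, "tibia": 0.226},
        name="fan toy",
        annotations={
            "synthetic": True,
            "strand_ma_m": radii,
            "expected_muscle_ma_m": float(np.mean(radii)),
        },
    )


def make_via_tangent_toy(r_m: float = 0.03, tangent_len_m: float = 1.2) -> LimbModel:
    """Via-point routing tangent below the hinge: MA = r at neutral.

    The crossing segment runs horizontally from a proximal via point at
    height ``-r`` to the insertion at the tangency point directly below
    the axis, so the neutral moment arm is exactly ``+r``.  Displacing the
    insertion radially outward by ``d`` gives
    ``MA(d) = c (r + d) / sqrt(c^2 + d^2)`` with ``c = tangent_len_m`` --
    approaching ``r + d`` as the tangent leg grows (the idealised pulley
    reading); the long default leg keeps the difference below 1e-6 m for
    millimetre offsets.
    """
    if not r_m > 0:
        raise ValueError(f"radius must be positive, got {r_m}")
    segments, joints = _hinge_skeleton()
    c = tangent_len_m
    paths = [
        MusclePath(
            muscle="tangent",
            strand="s1",
            points=[
                PathPoint("proximal", (-c - 0.1, -r_m, 0.0), "origin"),
                PathPoint("proximal", (-c, -r_m, 0.0), "via"),
                PathPoint("distal", (0.0, -r_m, 0.0), "insertion"),
            ],
        )
    ]
    arch = {"tangent": MuscleArchitecture("tangent", pcsa_m2=1e-4, donor_mass_kg=72.0)}
    return LimbModel(
        segments=segments,
        joints=joints,
        paths=paths,
        architecture=arch,
        body_mass_kg=72.0,
        bone_lengths_m={"femur": 0.271, "tibia": 0.226},
        name="via tangent toy",
        annotations={
            "synthetic": True,
            "expected_neutral_ma_m": r_m,
            "radial_offset_ma": lambda d, c=c, r=r_m: c * (r + d) / math.hypot(c, d),
        },
    )


def _planar_sign_change_deg(a_xy, b_xy) -> float:
    """Knee-convention sign-change angle from planar attachment geometry.

    For a crossing segment from a fixed point at planar position ``a``
    (relative to the hinge) to a moving point at ``b`` (neutral, child
    side), with the child rotating by ``-theta`` about world Z as the
    flexion angle theta grows, the moment arm vanishes when the two
    directions align: theta* = (atan2(b) - atan2(a)) mod 180 degrees.
    """
    phi_a = math.degrees(math.atan2(a_xy[1], a_xy[0]))
    phi_b = math.degrees(math.atan2(b_xy[1], b_xy[0]))
    return (phi_b - phi_a) % 180.0


def make_two_joint_toy(
    origin_offset_m: tuple[float, float] = (-0.018, 0.003),
) -> LimbModel:
    """Two-joint muscle whose distal-joint moment arm switches sign.

    Trunk-hip-thigh-knee-shank-ankle-foot chain at gorilla scale; the
    muscle originates on the thigh just posterior/superior to the knee
    (offset ``origin_offset_m`` in the sagittal plane, like a
    gastrocnemius head) and inserts on the heel.  Swept at the knee with
    the ankle locked, its moment arm starts flexor (negative) and crosses
    zero at the planar closed-form angle stored in
    ``annotations['expected_sign_change_deg']``; moving the origin away
    from the joint (superiorly) moves the crossing to a more flexed angle.
    """
    H = np.array([0.0, 0.497, 0.0])
    K = np.array([0.0, 0.226, 0.0])
    A = np.array([0.0, 0.0, 0.0])
    segments = {
        "trunk": Segment("trunk", None),
        "thigh": Segment("thigh", "trunk"),
        "shank": Segment("shank", "thigh"),
        "foot": Segment("foot", "shank"),
    }
    joints = {
        "hip": Joint("hip", "trunk", "thigh", H, np.eye(3),
                     {"fe": (-70.0, 145.0), "aa": (-25.0, 55.0)}),
        "knee": Joint("knee", "thigh", "shank", K, _MIRRORED_TRIAD,
                      {"fe": (-5.0, 150.0)}),
        "ankle": Joint("ankle", "shank", "foot", A, np.eye(3),
                       {"fe": (-30.0, 120.0), "aa": (-5.0, 25.0)}),
    }
    origin = K + np.array([origin_offset_m[0], origin_offset_m[1], 0.0])
    insertion = A + np.array([-0.045, -0.030, 0.0])
    paths = [
        MusclePath(
            muscle="two_joint",
            strand="s1",
            points=[
                PathPoint("thigh", origin, "origin"),
                PathPoint("foot", insertion, "insertion"),
            ],
        )
    ]
    arch = {
        "two_joint": MuscleArchitecture(
            "two_joint", mass_kg=0.45, fl_m=0.065, donor_mass_kg=72.0
        )
    }
    a_xy = (origin - K)[:2]
    b_xy = (insertion - K)[:2]
    return LimbModel(
        segments=segments,
        joints=joints,
        paths=paths,
        architecture=arch,
        body_mass_kg=72.0,
        bone_lengths_m={"femur": 0.271, "tibia": 0.226},
        name="two-joint toy",
        annotations={
            "synthetic": True,
            "expected_sign_change_deg": _planar_sign_change_deg(a_xy, b_xy),
            "neutral_sign": -1,
        },
    )


def _sample_point(rng, centre, lo, hi, keep_clear, min_dist=0.05):
    for _ in range(200):
        p = centre + rng.uniform(lo, hi, size=3)
        if all(np.linalg.norm(p - c) >= min_dist for c in keep_clear):
            return p
    raise RuntimeError("could not sample a point clear of the joint centres")


def make_random_model(seed: int, n_muscles: int = 5) -> LimbModel:
    """Seeded random three-segment limb for property suites.

    Trunk-thigh-shank chain with randomly oriented (proper, orthonormal)
    joint triads, muscles with random origins/vias/insertions kept at
    least 5 cm from the joint centres (keeps path curvature moderate), and
    random plausible architecture entries.  Via points only -- no wrap
    obstacles -- so the excursion and torque-projection moment-arm methods
    must agree to numerical precision.  The same seed reproduces the same
    model exactly.
    """
    rng = np.random.default_rng(seed)
    hipC = np.array([0.0, 0.50, 0.0]) + rng.uniform(-0.02, 0.02, 3)
    kneeC = np.array([0.0, 0.22, 0.0]) + rng.uniform(-0.02, 0.02, 3)

    def random_triad():
        from scipy.spatial.transform import Rotation

        return Rotation.from_rotvec(rng.normal(scale=0.4, size=3)).as_matrix()

    segments = {
        "trunk": Segment("trunk", None),
        "thigh": Segment("thigh", "trunk"),
        "shank": Segment("shank", "thigh"),
    }
    joints = {
        "hip": Joint("hip", "trunk", "thigh", hipC, random_triad(),
                     {"fe": (-80.0, 80.0), "aa": (-60.0, 60.0), "la": (-60.0, 60.0)}),
        "knee": Joint("knee", "thigh", "shank", kneeC, random_triad(),
                      {"fe": (-80.0, 80.0), "aa": (-60.0, 60.0), "la": (-60.0, 60.0)}),
    }
    clear = [hipC, kneeC]
    paths = []
    arch = {}
    for m in range(n_muscles):
        name = f"m{m + 1}"
        n_strands = int(rng.integers(1, 3))
        fractions = rng.dirichlet(np.ones(n_strands) * 5.0)
        for k in range(n_strands):
            pts = [
                PathPoint(
                    "trunk",
                    _sample_point(rng, hipC, -0.25, 0.25, clear),
                    "origin",
                )
            ]
            if rng.random() < 0.5:
                mid = 0.5 * (hipC + kneeC)
                pts.append(
                    PathPoint("thigh", _sample_point(rng, mid, -0.12, 0.12, clear), "via")
                )
            pts.append(
                PathPoint(
                    "shank",
                    _sample_point(
                        rng, kneeC + np.array([0.0, -0.12, 0.0]), -0.12, 0.12, clear
                    ),
                    "insertion",
                )
            )
            paths.append(
                MusclePath(name, f"s{k + 1}", pts, fraction=float(fractions[k]))
            )
        arch[name] = MuscleArchitecture(
            name,
            mass_kg=float(rng.uniform(0.05, 1.5)),
            fl_m=float(rng.uniform(0.05, 0.25)),
            donor_mass_kg=72.0,
        )
    return LimbModel(
        segments=segments,
        joints=joints,
        paths=paths,
        architecture=arch,
        body_mass_kg=72.0,
        bone_lengths_m={
            "femur": float(np.linalg.norm(hipC - kneeC)),
            "tibia": 0.226,
        },
        name=f"random model (seed {seed})",
        annotations={"synthetic": True, "seed": seed},
    )


def make_demo_hindlimb() -> LimbModel:
    """Synthetic gorilla-proportioned hind limb for the analysis pipeline.

    Four mobile segments (trunk, thigh, shank, rear foot; a rigid toes
    segment rides on the foot), hinge-convention hip/knee/ankle with the
    hip directly above the knee at neutral, femur 0.271 m and tibia
    0.226 m, and ten muscles (13 strands) with a plausible architecture
    table referred to a 72 kg donor.  The model is *synthetic*: no
    attachment was measured on a specimen.  Geometry is chosen so the
    standard comparative phenomenology emerges -- gluteals and hamstrings
    as hip extensors whose leverage falls with flexion, a knee dominated
    by the quadriceps, gastrocnemius heads arising just behind the knee
    that switch from knee flexor to extensor near 90 degrees of flexion
    (and later when their origins are shifted superiorly), and a rectus
    femoris arising below a horizontally oriented pelvis that switches
    from hip flexor to extensor at a flexed posture.
    """
    H = np.array([0.0, 0.497, 0.0])
    K = np.array([0.0, 0.226, 0.0])
    A = np.array([0.0, 0.0, 0.0])
    segments = {
        "trunk": Segment("trunk", None),
        "thigh": Segment("thigh", "trunk"),
        "shank": Segment("shank", "thigh"),
        "foot": Segment("foot", "shank"),
        "toes": Segment("toes", "foot"),  # rigid: no joint, held fixed
    }
    joints = {
        "hip": Joint("hip", "trunk", "thigh", H, np.eye(3),
                     {"fe": (-70.0, 145.0), "aa": (-25.0, 55.0), "la": (-30.0, 30.0)}),
        "knee": Joint("knee", "thigh", "shank", K, _MIRRORED_TRIAD,
                      {"fe": (-5.0, 150.0), "aa": (-10.0, 10.0)}),
        "ankle": Joint("ankle", "shank", "foot", A, np.eye(3),
                       {"fe": (-30.0, 115.0), "aa": (-5.0, 25.0)}),
    }

    def strand(muscle, sid, pts, wraps=(), fraction=1.0):
        return MusclePath(muscle, sid, pts, list(wraps), fraction)

    P = PathPoint
    paths = [
        # gluteus maximus: fan of three origins on the posterior pelvis
        strand("gluteus_maximus", "s1",
               [P("trunk", (-0.10, 0.560, -0.025), "origin"),
                P("thigh", (-0.03, 0.417, 0.005), "insertion")], fraction=1 / 3),
        strand("gluteus_maximus", "s2",
               [P("trunk", (-0.11, 0.545, 0.000), "origin"),
                P("thigh", (-0.03, 0.417, 0.005), "insertion")], fraction=1 / 3),
        strand("gluteus_maximus", "s3",
               [P("trunk", (-0.10, 0.530, 0.025), "origin"),
                P("thigh", (-0.03, 0.417, 0.005), "insertion")], fraction=1 / 3),
        # gluteus medius: two strands to the greater trochanter
        strand("gluteus_medius", "s1",
               [P("trunk", (-0.03, 0.560, 0.050), "origin"),
                P("thigh", (0.00, 0.470, 0.045), "insertion")], fraction=0.5),
        strand("gluteus_medius", "s2",
               [P("trunk", (0.01, 0.555, 0.050), "origin"),
                P("thigh", (0.00, 0.470, 0.045), "insertion")], fraction=0.5),
        strand("iliopsoas", "s1",
               [P("trunk", (0.06, 0.550, 0.010), "origin"),
                P("trunk", (0.03, 0.500, 0.005), "via", "hip rim"),
                P("thigh", (0.005, 0.450, -0.015), "insertion")]),
        # rectus femoris: origin just anterior-inferior to the hip
        # (horizontal pelvis), over the patella to the shank
        strand("rectus_femoris", "s1",
               [P("trunk", (0.025, 0.492, 0.000), "origin"),
                P("thigh", (0.050, 0.250, 0.000), "via", "patella"),
                P("shank", (0.040, 0.190, 0.000), "insertion")]),
        strand("vastus_lateralis", "s1",
               [P("thigh", (0.03, 0.420, 0.015), "origin"),
                P("thigh", (0.055, 0.245, 0.005), "via", "patella"),
                P("shank", (0.042, 0.190, 0.010), "insertion")],
               wraps=[WrapCylinder("thigh", K, (0.0, 0.0, 1.0), 0.042,
                                   side=-1, label="patellar groove")]),
        strand("biceps_femoris", "s1",
               [P("trunk", (-0.06, 0.470, 0.000), "origin"),
                P("shank", (-0.025, 0.190, 0.010), "insertion")]),
        # gastrocnemius heads: origins just behind/above the knee centre
        # the foot's neutral coordinates are the *fully plantarflexed*
        # posture (ankle angle 0 = fully extended, like the knee); the heel
        # then sits rotated up-back and the dorsum points down-forward
        strand("gastrocnemius", "medial",
               [P("thigh", (-0.018, 0.229, -0.015), "origin"),
                P("shank", (-0.035, 0.025, 0.000), "via", "achilles"),
                P("foot", (-0.0511, 0.0246, 0.000), "insertion", "heel")], fraction=0.5),
        strand("gastrocnemius", "lateral",
               [P("thigh", (-0.018, 0.229, 0.015), "origin"),
                P("shank", (-0.035, 0.025, 0.000), "via", "achilles"),
                P("foot", (-0.0511, 0.0246, 0.000), "insertion", "heel")], fraction=0.5),
        strand("soleus", "s1",
               [P("shank", (-0.030, 0.150, 0.000), "origin"),
                P("shank", (-0.035, 0.025, 0.000), "via", "achilles"),
                P("foot", (-0.0511, 0.0246, 0.000), "insertion", "heel")]),
        strand("tibialis_anterior", "s1",
               [P("shank", (0.035, 0.170, 0.000), "origin"),
                P("shank", (0.030, 0.120, 0.000), "via", "retinaculum"),
                P("foot", (0.019, -0.0552, -0.005), "insertion")]),
        strand("ext_digitorum", "s1",
               [P("shank", (0.035, 0.180, 0.010), "origin"),
                P("shank", (0.028, 0.110, 0.005), "via", "retinaculum"),
                P("foot", (0.0311, -0.0718, 0.005), "insertion")]),
    ]

    donor = 72.0
    arch_rows = [
        ("gluteus_maximus", 1.20, 0.140),
        ("gluteus_medius", 0.90, 0.090),
        ("iliopsoas", 0.50, 0.120),
        ("rectus_femoris", 0.35, 0.100),
        ("vastus_lateralis", 1.00, 0.095),
        ("biceps_femoris", 0.60, 0.130),
        ("gastrocnemius", 0.45, 0.065),
        ("soleus", 0.50, 0.045),
        ("tibialis_anterior", 0.25, 0.070),
        ("ext_digitorum", 0.15, 0.080),
    ]
    architecture = {
        name: MuscleArchitecture(name, mass_kg=m, fl_m=fl, donor_mass_kg=donor)
        for name, m, fl in arch_rows
    }

    gastroc_a = np.array([-0.018, 0.229, 0.0]) - K
    gastroc_b = np.array([-0.035, 0.025, 0.0]) - K  # crossing anchor: achilles via
    rf_a = np.array([0.025, 0.492, 0.0]) - H
    rf_b = np.array([0.050, 0.250, 0.0]) - H
    return LimbModel(
        segments=segments,
        joints=joints,
        paths=paths,
        architecture=architecture,
        body_mass_kg=152.0,
        bone_lengths_m={"femur": 0.271, "tibia": 0.226},
        name="synthetic demo hindlimb",
        annotations={
            "synthetic": True,
            "donor_mass_kg": donor,
            "gastrocnemius_knee_sign_change_deg": _planar_sign_change_deg(
                gastroc_a[:2], gastroc_b[:2]
            ),
            # hip convention rotates the child by +theta, so the closed form
            # swaps the fixed/moving roles relative to the knee formula
            "rectus_femoris_hip_sign_change_deg": (
                -_planar_sign_change_deg(rf_a[:2], rf_b[:2])
            ) % 180.0,
        },
    )
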