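"""Signed muscle moment arms by tendon excursion and by torque projection.

Both methods share the sign convention of the output figures: a muscle
that lengthens as the joint flexes (an extensor) has a positive moment
arm, a flexor a negative one.  With each joint's triad oriented so that a
positive flexion-extension angle flexes the joint, this is simply
``MA = dL/dtheta`` with theta in radians.

The two methods are mathematically equivalent for taut paths:

* excursion: central difference of the routed path length over the joint
  angle (the numerical analogue of the experimental tendon-travel method);
* geometric: for every straight path segment with endpoints a, b and unit
  direction u, the end bound to the moving (distal) subtree contributes
  ``+/- axis . ((x - c) x u)`` -- the lever of the line of action about the
  joint centre c.  Wrap tangent points ride on the cylinder's segment, and
  the surface geodesic connects two points of one rigid body so it drops
  out of the derivative (envelope property of the shortest route).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import LimbModel, MusclePath, Pose
from .kinematics import (
    DEFAULT_EULER_ORDER,
    joint_world_geometry,
    route_strand,
)

__all__ = [
    "MomentArmCurve",
    "SweepSpec",
    "moment_arm_excursion",
    "moment_arm_geometric",
    "muscle_moment_arm",
    "sweep_moment_arms",
    "DEFAULT_STEP_DEG",
]

#: Central-difference step for the excursion method.  Small enough that the
#: quadratic truncation error is far below 1e-6 m on desk-scale geometry.
DEFAULT_STEP_DEG = 0.1

#: Bone used to normalise moment arms per joint (divide MA by this length).
NORMALISE_BONE = {"hip": "femur", "knee": "femur", "ankle": "tibia"}


@dataclass
class SweepSpec:
    """One-joint-at-a-time sweep: grid over one axis, all else locked."""

    joint: str
    start_deg: float
    stop_deg: float
    step_deg: float = 10.0
    axis: str = "fe"
    locked: dict[tuple[str, str], float] = field(default_factory=dict)
    label: str = ""
    allow_out_of_range: bool = False

    @property
    def grid(self) -> np.ndarray:
        if self.step_deg <= 0 or self.stop_deg < self.start_deg:
            raise ValueError(
                f"sweep grid is empty ({self.start_deg}:{self.stop_deg}:"
                f"{self.step_deg})"
            )
        n = int(round((self.stop_deg - self.start_deg) / self.step_deg))
        return self.start_deg + self.step_deg * np.arange(n + 1)

    def pose_at(self, angle_deg: float) -> Pose:
        pose = Pose(allow_out_of_range=self.allow_out_of_range)
        for (joint, axis), value in self.locked.items():
            pose.set_angle(joint, axis, value)
        pose.set_angle(self.joint, self.axis, angle_deg)
        return pose

    def lock_descriptor(self) -> str:
        if self.label:
            return self.label
        return ",".join(
            f"{j}.{a}={v:g}" for (j, a), v in sorted(self.locked.items())
        ) or "neutral"


@dataclass
class MomentArmCurve:
    """Signed moment arm (and optionally torque) versus joint angle."""

    joint: str
    entity: str
    kind: str                      # strand | muscle | group
    lock: str
    angles_deg: np.ndarray
    ma_m: np.ndarray
    norm_bone: str | None = None
    ma_norm: np.ndarray | None = None
    pcsa_m2: float | None = None
    torque_nm: np.ndarray | None = None
    fpua_nm2: float | None = None

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.ma_m = np.asarray(self.ma_m, dtype=float)
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("curve angle grid must be strictly increasing")
        if not np.all(np.isfinite(self.ma_m)):
            raise ValueError("curve values must be finite")


def _crosses_joint(model: LimbModel, strand: MusclePath, joint_name: str) -> bool:
    """True iff the strand has bound entities on both sides of the joint."""
    distal = model.distal_segments(joint_name)
    bound = {p.segment for p in strand.points} | {w.segment for w in strand.wraps}
    return bool(bound & distal) and bool(bound - distal)


def moment_arm_excursion(
    model: LimbModel,
    pose: Pose,
    strand: MusclePath,
    joint: str,
    axis: str = "fe",
    h_deg: float = DEFAULT_STEP_DEG,
    euler_order: str = DEFAULT_EULER_ORDER,
) -> float:
    """Moment arm as dL/dtheta by central difference (tendon excursion).

    Strands that do not cross the joint return exactly 0.  When the pose
    sits at a joint limit such that one probe would leave the limits, the
    difference falls back to one-sided and a warning is issued.
    """
    if not _crosses_joint(model, strand, joint):
        return 0.0
    j = model.joints[joint]
    theta = pose.angle(joint, axis)
    lo, hi = j.axis_limits(axis)
    lo_ok = theta - h_deg >= lo - 1e-9
    hi_ok = theta + h_deg <= hi + 1e-9
    h_rad = np.deg2rad(h_deg)

    def L(angle):
        probe = pose.with_angle(joint, axis, angle)
        probe.allow_out_of_range = True
        return route_strand(model, probe, strand, euler_order).length

    if lo_ok and hi_ok:
        return (L(theta + h_deg) - L(theta - h_deg)) / (2.0 * h_rad)
    warnings.warn(
        f"{strand.muscle}/{strand.strand}: {joint}:{axis} at {theta} deg is at a "
        "joint limit; using one-sided excursion difference",
        stacklevel=2,
    )
    if hi_ok:
        return (L(theta + h_deg) - L(theta)) / h_rad
    return (L(theta) - L(theta - h_deg)) / h_rad


def moment_arm_geometric(
    model: LimbModel,
    pose: Pose,
    strand: MusclePath,
    joint: str,
    axis: str = "fe",
    euler_order: str = DEFAULT_EULER_ORDER,
) -> float:
    """Moment arm from the path's lines of action about the joint axis."""
    if not _crosses_joint(model, strand, joint):
        return 0.0
    centre, ax = joint_world_geometry(model, pose, joint, axis, euler_order)
    distal = model.distal_segments(joint)
    routed = route_strand(model, pose, strand, euler_order)
    ma = 0.0
    for a, b in routed.straight_spans:
        pa, pb = routed.points[a], routed.points[b]
        u = pb - pa
        norm = np.linalg.norm(u)
        if norm == 0.0:
            continue
        u = u / norm
        if routed.bound_segments[b] in distal:
            ma += float(ax @ np.cross(pb - centre, u))
        if routed.bound_segments[a] in distal:
            ma -= float(ax @ np.cross(pa - centre, u))
    return ma


def muscle_moment_arm(
    model: LimbModel,
    pose: Pose,
    muscle: str,
    joint: str,
    axis: str = "fe",
    method: str = "excursion",
    **kw,
) -> float:
    """PCSA-fraction-weighted mean of the muscle's strand moment arms."""
    strands = model.muscles().get(muscle)
    if not strands:
        raise KeyError(f"model has no muscle {muscle!r}")
    f = {"excursion": moment_arm_excursion, "geometric": moment_arm_geometric}[method]
    total_frac = sum(s.fraction for s in strands)
    return sum(
        s.fraction * f(model, pose, s, joint, axis, **kw) for s in strands
    ) / total_frac


def sweep_moment_arms(
    model: LimbModel,
    sweep: SweepSpec,
    method: str = "excursion",
    include_muscle_curves: bool = True,
    euler_order: str = DEFAULT_EULER_ORDER,
) -> list[MomentArmCurve]:
    """One-joint-at-a-time sweep: a curve per strand (and per muscle).

    The locked posture (e.g. a hip abduction setting) applies at every
    grid point; the swept axis takes the grid value.  Muscle-level curves
    are the PCSA-fraction-weighted means of their strand curves; raw
    strand curves are always produced.
    """
    grid = sweep.grid
    f = {"excursion": moment_arm_excursion, "geometric": moment_arm_geometric}[method]
    lock = sweep.lock_descriptor()
    bone = NORMALISE_BONE.get(sweep.joint)
    bone_len = model.bone_lengths_m.get(bone) if bone else None

    curves: list[MomentArmCurve] = []
    per_muscle: dict[str, list[tuple[float, np.ndarray]]] = {}
    for strand in model.paths:
        ma = np.array([
            f(model, sweep.pose_at(a), strand, sweep.joint, sweep.axis,
              euler_order=euler_order)
            for a in grid
        ])
        pcsa = None
        if strand.muscle in model.architecture:
            pcsa = model.strand_pcsa(strand)
        curves.append(
            MomentArmCurve(
                joint=sweep.joint,
                entity=f"{strand.muscle}/{strand.strand}",
                kind="strand",
                lock=lock,
                angles_deg=grid,
                ma_m=ma,
                norm_bone=bone,
                ma_norm=ma / bone_len if bone_len else None,
                pcsa_m2=pcsa,
            )
        )
        per_muscle.setdefault(strand.muscle, []).append((strand.fraction, ma))

    if include_muscle_curves:
        for muscle, parts in per_muscle.items():
            wsum = sum(w for w, _ in parts)
            ma = sum(w * m for w, m in parts) / wsum
            pcsa = None
            if muscle in model.architecture:
                pcsa = model.architecture[muscle].pcsa()
            curves.append(
                MomentArmCurve(
                    joint=sweep.joint,
                    entity=muscle,
                    kind="muscle",
                    lock=lock,
                    angles_deg=grid,
                    ma_m=ma,
                    norm_bone=bone,
                    ma_norm=ma / bone_len if bone_len else None,
                    pcsa_m2=pcsa,
                )
            )
    return curves
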