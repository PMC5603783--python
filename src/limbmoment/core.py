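"""Domain types for rigid-segment musculoskeletal limb models.

A :class:`LimbModel` is a tree of rigid segments connected by joints, with
muscle--tendon paths routed over the segments through attachment points,
via points and cylindrical wrap obstacles, plus a muscle-architecture table
(mass, fascicle length, physiological cross-sectional area).

Conventions
-----------
* Units at the API surface: metres, kilograms, degrees.
* Every segment's local frame coincides with the world frame at the neutral
  posture, so attachment coordinates are simply neutral-posture world
  coordinates tagged with the segment that carries them.
* Each joint has a right-handed axis triad: Z is the flexion--extension
  axis, X abduction--adduction, Y long-axis rotation.  Models orient each
  triad so that a *positive* flexion--extension angle flexes the joint
  (hip: positive flexed / negative extended; knee and ankle: zero fully
  extended, increasing angle more flexed / dorsiflexed).  With that
  orientation a muscle that lengthens during flexion -- an extensor -- has a
  positive moment arm, which is the sign convention of all outputs.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Segment",
    "Joint",
    "Pose",
    "PathPoint",
    "WrapCylinder",
    "MusclePath",
    "MuscleArchitecture",
    "LimbModel",
    "ValidationReport",
    "validate_model",
    "MUSCLE_DENSITY_KG_M3",
]

#: Literature-standard skeletal muscle density used to turn mass into volume.
MUSCLE_DENSITY_KG_M3 = 1060.0

_AXIS_NAMES = ("fe", "aa", "la")
#: Column of the joint triad matrix used by each rotation: X = ab-adduction,
#: Z = flexion-extension, Y = long-axis rotation.
_AXIS_COLUMN = {"aa": 0, "la": 1, "fe": 2}


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass
class Segment:
    """A rigid body of the limb (trunk, thigh, shank, foot, ...)."""

    name: str
    parent: str | None = None  # None marks the root (pelvis/trunk)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("segment needs a non-empty name")


@dataclass
class Joint:
    """Hinge/ball joint between a parent and a child segment.

    ``centre`` is expressed in the parent frame at neutral; ``axes`` is a
    3x3 right-handed orthonormal matrix whose columns are the X
    (ab-adduction), Y (long-axis) and Z (flexion-extension) axes in the
    parent frame at neutral.  ``limits_deg`` maps axis key ('fe', 'aa',
    'la') to an (lo, hi) pair in degrees.
    """

    name: str
    parent_segment: str
    child_segment: str
    centre: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    limits_deg: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centre = _as_vec3(self.centre)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)

    def axis_limits(self, axis: str) -> tuple[float, float]:
        return self.limits_deg.get(axis, (-180.0, 180.0))


@dataclass
class Pose:
    """Joint-angle assignment: per joint a (fe, aa, la) triple in degrees.

    Angles default to zero (the neutral posture).  ``allow_out_of_range``
    permits angles outside joint limits; otherwise :func:`validate_pose`
    and the sweep machinery will complain.
    """

    angles: dict[str, dict[str, float]] = field(default_factory=dict)
    allow_out_of_range: bool = False

    @classmethod
    def neutral(cls) -> "Pose":
        return cls()

    def angle(self, joint: str, axis: str = "fe") -> float:
        if axis not in _AXIS_NAMES:
            raise ValueError(f"unknown axis {axis!r}; expected one of {_AXIS_NAMES}")
        return self.angles.get(joint, {}).get(axis, 0.0)

    def set_angle(self, joint: str, axis: str, value_deg: float) -> "Pose":
        if axis not in _AXIS_NAMES:
            raise ValueError(f"unknown axis {axis!r}; expected one of {_AXIS_NAMES}")
        self.angles.setdefault(joint, {})[axis] = float(value_deg)
        return self

    def with_angle(self, joint: str, axis: str, value_deg: float) -> "Pose":
        """Return a copy with one angle replaced (the original is untouched)."""
        new = Pose(copy.deepcopy(self.angles), self.allow_out_of_range)
        return new.set_angle(joint, axis, value_deg)

    def triple(self, joint: str) -> tuple[float, float, float]:
        return tuple(self.angle(joint, a) for a in _AXIS_NAMES)


@dataclass
class PathPoint:
    """A segment-bound routing point of a muscle strand."""

    segment: str
    location: np.ndarray
    role: str = "via"  # origin | via | insertion
    label: str = ""

    def __post_init__(self) -> None:
        self.location = _as_vec3(self.location)


@dataclass
class WrapCylinder:
    """Cylindrical wrap obstacle bound to a segment.

    ``side`` selects the sense in which the path passes around the axis:
    +1 wraps right-handed (counter-clockwise looking down the axis
    direction), -1 left-handed, ``None`` lets the router take the shorter
    route.
    """

    segment: str
    origin: np.ndarray
    direction: np.ndarray
    radius: float
    side: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.origin = _as_vec3(self.origin)
        self.direction = _as_vec3(self.direction)


@dataclass
class MusclePath:
    """One strand of a muscle: ordered attachment points plus obstacles.

    Fan-shaped muscles are modelled as several strands that converge on a
    shared insertion; ``fraction`` is the strand's share of the muscle's
    PCSA (strands of one muscle sum to 1).
    """

    muscle: str
    strand: str
    points: list[PathPoint]
    wraps: list[WrapCylinder] = field(default_factory=list)
    fraction: float = 1.0

    @property
    def origin(self) -> PathPoint:
        return self.points[0]

    @property
    def insertion(self) -> PathPoint:
        return self.points[-1]


@dataclass
class MuscleArchitecture:
    """Architecture record: mass, fascicle length and PCSA of one muscle.

    ``pcsa_m2`` may be given directly (e.g. from a published table) or left
    ``None`` to be computed as (mass / density) / FL.  ``donor_mass_kg`` is
    the body mass of the animal the measurements come from; geometric
    scaling to another body mass is done by
    :func:`limbmoment.architecture.scale_architecture`.
    """

    muscle: str
    mass_kg: float | None = None
    fl_m: float | None = None
    tendon_m: float | None = None
    pcsa_m2: float | None = None
    donor_mass_kg: float | None = None

    def pcsa(self, density: float = MUSCLE_DENSITY_KG_M3) -> float:
        if self.pcsa_m2 is not None:
            return float(self.pcsa_m2)
        if self.mass_kg is None or self.fl_m is None:
            raise ValueError(
                f"architecture for {self.muscle!r} has neither PCSA nor mass+FL"
            )
        return (self.mass_kg / density) / self.fl_m


@dataclass
class LimbModel:
    """A complete musculoskeletal limb model."""

    segments: dict[str, Segment]
    joints: dict[str, Joint]
    paths: list[MusclePath]
    architecture: dict[str, MuscleArchitecture] = field(default_factory=dict)
    body_mass_kg: float | None = None
    bone_lengths_m: dict[str, float] = field(default_factory=dict)
    name: str = "limb model"
    annotations: dict = field(default_factory=dict)

    # -- structure helpers -------------------------------------------------
    def root(self) -> str:
        roots = [s.name for s in self.segments.values() if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"model must have exactly one root segment, found {roots}")
        return roots[0]

    def joint_for_child(self, segment: str) -> Joint | None:
        for j in self.joints.values():
            if j.child_segment == segment:
                return j
        return None

    def children(self, segment: str) -> list[str]:
        return [s.name for s in self.segments.values() if s.parent == segment]

    def distal_segments(self, joint: str | Joint) -> frozenset[str]:
        """All segments on the child side of ``joint`` (the moving subtree)."""
        j = self.joints[joint] if isinstance(joint, str) else joint
        out: set[str] = set()
        stack = [j.child_segment]
        while stack:
            s = stack.pop()
            if s in out:
                continue
            out.add(s)
            stack.extend(self.children(s))
        return frozenset(out)

    def muscles(self) -> dict[str, list[MusclePath]]:
        """Strands grouped by muscle, preserving insertion-file order."""
        out: dict[str, list[MusclePath]] = {}
        for p in self.paths:
            out.setdefault(p.muscle, []).append(p)
        return out

    def strand_pcsa(self, path: MusclePath,
                    density: float = MUSCLE_DENSITY_KG_M3) -> float:
        arch = self.architecture.get(path.muscle)
        if arch is None:
            raise KeyError(f"no architecture entry for muscle {path.muscle!r}")
        return arch.pcsa(density) * path.fraction

    def copy(self) -> "LimbModel":
        return copy.deepcopy(self)


@dataclass
class ValidationReport:
    """Result of :func:`validate_model`: a list of human-readable violations."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok

    def __iter__(self):
        return iter(self.violations)


def _finite(x: Iterable[float]) -> bool:
    return bool(np.all(np.isfinite(np.asarray(list(x), dtype=float))))


def validate_model(model: LimbModel) -> ValidationReport:
    """Check every structural invariant of the model; report, don't raise.

    Returns an empty report iff the model is valid.  Checks: the segment
    graph is a tree rooted at a single trunk segment; joints and paths
    reference existing segments; joint triads are right-handed orthonormal
    with ordered limits; strand PCSA fractions lie in (0, 1] and sum to 1
    per muscle; wrap cylinders have positive radius and unit axis; the
    architecture table is positive and internally consistent (given PCSA
    within 5% of (mass/density)/FL when both forms are present).
    """
    v: list[str] = []
    seg_names = set(model.segments)

    # Segment tree: single root, parents exist, acyclic by traversal.
    roots = [s.name for s in model.segments.values() if s.parent is None]
    if len(roots) != 1:
        v.append(f"segment graph must have exactly one root, found {sorted(roots)}")
    for s in model.segments.values():
        if s.parent is not None and s.parent not in seg_names:
            v.append(f"segment {s.name!r} has unknown parent {s.parent!r}")
    # cycle check: walk up from every segment
    for s in model.segments.values():
        seen = {s.name}
        cur = s.parent
        while cur is not None:
            if cur in seen:
                v.append(f"segment graph contains a cycle through {cur!r}")
                break
            seen.add(cur)
            cur = model.segments[cur].parent if cur in seg_names else None

    for j in model.joints.values():
        for nm, role in ((j.parent_segment, "parent"), (j.child_segment, "child")):
            if nm not in seg_names:
                v.append(f"joint {j.name!r} references unknown {role} segment {nm!r}")
        if not _finite(j.centre):
            v.append(f"joint {j.name!r} centre is not finite")
        if not np.allclose(j.axes.T @ j.axes, np.eye(3), atol=1e-9):
            v.append(f"joint {j.name!r} axes are not orthonormal")
        elif np.linalg.det(j.axes) < 0:
            v.append(f"joint {j.name!r} axes are left-handed")
        for axis, (lo, hi) in j.limits_deg.items():
            if lo > hi:
                v.append(f"joint {j.name!r} limits on {axis!r} are unordered ({lo} > {hi})")

    fractions: dict[str, float] = {}
    for p in model.paths:
        pid = f"{p.muscle}/{p.strand}"
        if len(p.points) < 2:
            v.append(f"strand {pid} has fewer than 2 path points")
        for pt in p.points:
            if pt.segment not in seg_names:
                v.append(
                    f"strand {pid} point {pt.label or pt.role!r} is bound to "
                    f"unknown segment {pt.segment!r}"
                )
            if not _finite(pt.location):
                v.append(f"strand {pid} point {pt.label or pt.role!r} is not finite")
        for w in p.wraps:
            if w.segment not in seg_names:
                v.append(f"strand {pid} wrap is bound to unknown segment {w.segment!r}")
            if not w.radius > 0:
                v.append(f"strand {pid} wrap radius must be positive, got {w.radius}")
            if abs(np.linalg.norm(w.direction) - 1.0) > 1e-6:
                v.append(f"strand {pid} wrap direction is not unit length")
        if not (0.0 < p.fraction <= 1.0):
            v.append(f"strand {pid} PCSA fraction {p.fraction} outside (0, 1]")
        fractions[p.muscle] = fractions.get(p.muscle, 0.0) + p.fraction
    for muscle, total in fractions.items():
        if abs(total - 1.0) > 1e-6:
            v.append(f"muscle {muscle!r} strand fractions sum to {total:.6g}, not 1")

    for arch in model.architecture.values():
        for fname in ("mass_kg", "fl_m", "tendon_m", "pcsa_m2", "donor_mass_kg"):
            val = getattr(arch, fname)
            if val is not None and not val > 0:
                v.append(f"architecture {arch.muscle!r}: {fname} must be positive, got {val}")
        if arch.pcsa_m2 is not None and arch.mass_kg is not None and arch.fl_m is not None:
            implied = (arch.mass_kg / MUSCLE_DENSITY_KG_M3) / arch.fl_m
            if abs(arch.pcsa_m2 - implied) > 0.05 * implied:
                v.append(
                    f"architecture {arch.muscle!r}: given PCSA {arch.pcsa_m2:.4g} m^2 "
                    f"deviates >5% from (mass/density)/FL = {implied:.4g} m^2"
                )

    if model.body_mass_kg is not None and not model.body_mass_kg > 0:
        v.append(f"body mass must be positive, got {model.body_mass_kg}")
    for bone, length in model.bone_lengths_m.items():
        if not (math.isfinite(length) and length > 0):
            v.append(f"bone length {bone!r} must be positive and finite, got {length}")

    return ValidationReport(v)


def validate_pose(model: LimbModel, pose: Pose) -> list[str]:
    """Angles outside joint limits (empty when valid or overridden)."""
    if pose.allow_out_of_range:
        return []
    bad = []
    for jname, axes in pose.angles.items():
        j = model.joints.get(jname)
        if j is None:
            bad.append(f"pose references unknown joint {jname!r}")
            continue
        for axis, value in axes.items():
            lo, hi = j.axis_limits(axis)
            if not (lo - 1e-9 <= value <= hi + 1e-9):
                bad.append(
                    f"{jname}:{axis} = {value} deg outside limits [{lo}, {hi}]"
                )
    return bad
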