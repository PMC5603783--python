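"""Posing the limb and routing muscle paths in world coordinates.

Joint rotations compose intrinsically X (ab-adduction) then Z
(flexion-extension) then Y (long-axis rotation) in the joint's own triad;
the order is a documented model convention (sweeps hold ab-adduction fixed
while flexion varies, which this order makes well defined) and can be
changed per call via ``euler_order``.

Muscle paths are polylines through segment-bound points; a path segment
obstructed by a cylindrical wrap obstacle is replaced by the shortest
tangent--geodesic--tangent route over the cylinder surface (the standard
obstacle-set construction: unroll the cylinder, the routed path is a
straight line in the unrolled plane).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import LimbModel, MusclePath, Pose, WrapCylinder

__all__ = [
    "segment_transforms",
    "segment_transform",
    "transform_point",
    "joint_world_geometry",
    "path_points_world",
    "wrap_route",
    "WrapResult",
    "RoutedPath",
    "route_strand",
    "path_length",
    "strand_length",
    "DEFAULT_EULER_ORDER",
]

DEFAULT_EULER_ORDER = "XZY"  # intrinsic: ab-adduction, flexion-extension, long-axis

_ANGLE_FOR_LETTER = {"X": "aa", "Z": "fe", "Y": "la"}


def _local_rotation(pose: Pose, joint_name: str, order: str) -> np.ndarray:
    angles = [pose.angle(joint_name, _ANGLE_FOR_LETTER[c]) for c in order]
    return Rotation.from_euler(order, angles, degrees=True).as_matrix()


def segment_transforms(
    model: LimbModel, pose: Pose, euler_order: str = DEFAULT_EULER_ORDER
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """World rigid transform (R, t) of every segment for ``pose``.

    Segment frames coincide with the world frame at neutral, so each
    transform maps neutral-posture coordinates to posed world coordinates.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    root = model.root()
    out[root] = (np.eye(3), np.zeros(3))

    def visit(seg: str) -> None:
        for child in model.children(seg):
            joint = model.joint_for_child(child)
            Rp, tp = out[seg]
            if joint is None:
                # rigidly attached (e.g. intra-foot segments held fixed)
                out[child] = (Rp, tp)
            else:
                A = joint.axes
                Rl = A @ _local_rotation(pose, joint.name, euler_order) @ A.T
                c = joint.centre
                Rc = Rp @ Rl
                tc = Rp @ (c - Rl @ c) + tp
                out[child] = (Rc, tc)
            visit(child)

    visit(root)
    return out


def segment_transform(
    model: LimbModel, pose: Pose, segment: str,
    euler_order: str = DEFAULT_EULER_ORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """World transform of one segment (unknown segment -> KeyError)."""
    if segment not in model.segments:
        raise KeyError(f"unknown segment {segment!r}")
    return segment_transforms(model, pose, euler_order)[segment]


def transform_point(tf: tuple[np.ndarray, np.ndarray], x) -> np.ndarray:
    R, t = tf
    return R @ np.asarray(x, dtype=float) + t


def joint_world_geometry(
    model: LimbModel, pose: Pose, joint_name: str, axis: str = "fe",
    euler_order: str = DEFAULT_EULER_ORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """World joint centre and instantaneous world rotation axis.

    For the intrinsic X-Z-Y composition the instantaneous flexion axis at
    ab-adduction angle ``aa`` is ``A @ Rx(aa) @ z`` (the X axis is fixed,
    the Y axis additionally carries the flexion rotation), mapped through
    the parent's world rotation.
    """
    joint = model.joints[joint_name]
    tfs = segment_transforms(model, pose, euler_order)
    Rp, tp = tfs[joint.parent_segment]
    A = joint.axes
    aa = pose.angle(joint_name, "aa")
    fe = pose.angle(joint_name, "fe")
    if euler_order != "XZY":
        # generic fallback: finite-difference-free derivation is only wired
        # for the default order; other orders use the raw triad axis.
        local = {"aa": A[:, 0], "fe": A[:, 2], "la": A[:, 1]}[axis]
        return Rp @ joint.centre + tp, Rp @ local
    Rx = Rotation.from_euler("X", aa, degrees=True).as_matrix()
    if axis == "aa":
        local = A[:, 0]
    elif axis == "fe":
        local = A @ Rx @ np.array([0.0, 0.0, 1.0])
    elif axis == "la":
        Rz = Rotation.from_euler("Z", fe, degrees=True).as_matrix()
        local = A @ Rx @ Rz @ np.array([0.0, 1.0, 0.0])
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return Rp @ joint.centre + tp, Rp @ local


def path_points_world(
    model: LimbModel, pose: Pose, strand: MusclePath,
    euler_order: str = DEFAULT_EULER_ORDER,
) -> np.ndarray:
    """World coordinates of the strand's attachment/via points, in order."""
    tfs = segment_transforms(model, pose, euler_order)
    return np.array([transform_point(tfs[p.segment], p.location) for p in strand.points])


# ---------------------------------------------------------------------------
# cylindrical wrapping
# ---------------------------------------------------------------------------

@dataclass
class WrapResult:
    """Route of one path segment past one cylinder."""

    points: np.ndarray          # (2,3) straight or (4,3) p, t1, t2, q
    length: float
    wrapped: bool
    wrap_angle_rad: float = 0.0
    side: int = 0


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed (e1, e2) completion of a unit axis."""
    d = direction / np.linalg.norm(direction)
    k = int(np.argmin(np.abs(d)))
    e1 = np.zeros(3)
    e1[k] = 1.0
    e1 = e1 - (e1 @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _perp2(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def _seg_point_dist2(P: np.ndarray, Q: np.ndarray) -> float:
    """2D distance from the origin to segment PQ."""
    d = Q - P
    dd = d @ d
    if dd == 0.0:
        return float(np.hypot(*P))
    t = np.clip(-(P @ d) / dd, 0.0, 1.0)
    c = P + t * d
    return float(np.hypot(*c))


def _wrap_one_side(P, Q, pz, qz, r, s):
    """Tangent-geodesic-tangent route with wrap sense ``s`` (+1 = CCW)."""
    dp2, dq2 = P @ P, Q @ Q
    Lp = np.sqrt(max(dp2 - r * r, 0.0))
    Lq = np.sqrt(max(dq2 - r * r, 0.0))
    T1 = (r * r * P + s * r * Lp * _perp2(P)) / dp2
    T2 = (r * r * Q - s * r * Lq * _perp2(Q)) / dq2
    a1 = np.arctan2(T1[1], T1[0])
    a2 = np.arctan2(T2[1], T2[0])
    phi = (s * (a2 - a1)) % (2.0 * np.pi)
    U = Lp + r * phi + Lq
    dz = qz - pz
    length = float(np.hypot(U, dz))
    if U > 0:
        z1 = pz + dz * Lp / U
        z2 = pz + dz * (Lp + r * phi) / U
    else:  # degenerate: endpoints on the surface at the same station
        z1, z2 = pz, qz
    return T1, T2, float(phi), length, z1, z2


def wrap_route(p, q, cylinder: WrapCylinder, tf=None) -> WrapResult:
    """Route the segment p->q past ``cylinder`` (world coordinates).

    If ``tf`` is given, the cylinder's segment-frame origin/direction are
    first mapped through that rigid transform.  Returns the straight
    segment (``wrapped=False``) whenever the segment's closest approach to
    the axis is at least the radius; otherwise the shortest
    tangent--geodesic--tangent route on the requested side (``cylinder.side``;
    ``None`` picks the shorter side).

    Raises ``ValueError`` when either endpoint lies strictly inside the
    cylinder (degenerate geometry).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    o = cylinder.origin
    d = cylinder.direction / np.linalg.norm(cylinder.direction)
    e1l, e2l = _perp_basis(d)
    if tf is not None:
        R, t = tf
        o = R @ o + t
        d, e1, e2 = R @ d, R @ e1l, R @ e2l
    else:
        e1, e2 = e1l, e2l
    r = float(cylinder.radius)

    def to_local(x):
        rel = x - o
        return np.array([rel @ e1, rel @ e2]), float(rel @ d)

    P, pz = to_local(p)
    Q, qz = to_local(q)
    tol = 1e-9
    for name, X in (("p", P), ("q", Q)):
        if np.hypot(*X) < r - tol:
            raise ValueError(
                f"path point {name} lies inside wrap cylinder "
                f"{cylinder.label or cylinder.segment!r} (radius {r} m)"
            )

    straight = WrapResult(
        points=np.vstack([p, q]), length=float(np.linalg.norm(q - p)), wrapped=False
    )
    if _seg_point_dist2(P, Q) >= r:
        return straight

    sides = (cylinder.side,) if cylinder.side in (-1, 1) else (1, -1)
    best = None
    for s in sides:
        T1, T2, phi, length, z1, z2 = _wrap_one_side(P, Q, pz, qz, r, s)
        if best is None or length < best[0]:
            best = (length, s, T1, T2, phi, z1, z2)
    length, s, T1, T2, phi, z1, z2 = best

    def to_world(X2, z):
        return o + X2[0] * e1 + X2[1] * e2 + z * d

    t1w = to_world(T1, z1)
    t2w = to_world(T2, z2)
    return WrapResult(
        points=np.vstack([p, t1w, t2w, q]),
        length=length,
        wrapped=True,
        wrap_angle_rad=phi,
        side=s,
    )


# ---------------------------------------------------------------------------
# routed paths and lengths
# ---------------------------------------------------------------------------

@dataclass
class RoutedPath:
    """A strand routed at one pose.

    ``points`` are world coordinates; ``bound_segments`` names the rigid
    body each point rides on (wrap tangent points ride on the cylinder's
    segment).  ``straight_spans`` lists index pairs (i, i+1) connected by
    straight line segments; spans covered by a surface geodesic instead
    appear in ``arc_lengths`` keyed by the leading index.
    """

    points: np.ndarray
    bound_segments: list[str]
    straight_spans: list[tuple[int, int]]
    arc_lengths: dict[int, float] = field(default_factory=dict)

    @property
    def length(self) -> float:
        total = sum(
            float(np.linalg.norm(self.points[b] - self.points[a]))
            for a, b in self.straight_spans
        )
        return total + sum(self.arc_lengths.values())


def route_strand(
    model: LimbModel, pose: Pose, strand: MusclePath,
    euler_order: str = DEFAULT_EULER_ORDER,
) -> RoutedPath:
    """Pose the strand and resolve wrap obstacles segment by segment.

    Consecutive coincident points are dropped with a warning (degenerate
    zero-length path pieces carry no geometric information).  For each
    remaining consecutive pair the first engaging cylinder (in the
    strand's ``wraps`` order) supplies the route.
    """
    tfs = segment_transforms(model, pose, euler_order)
    pts: list[np.ndarray] = []
    segs: list[str] = []
    for p in strand.points:
        w = transform_point(tfs[p.segment], p.location)
        if pts and np.linalg.norm(w - pts[-1]) < 1e-12:
            warnings.warn(
                f"strand {strand.muscle}/{strand.strand}: dropped coincident "
                f"path point {p.label or p.role!r}",
                stacklevel=2,
            )
            continue
        pts.append(w)
        segs.append(p.segment)

    out_pts: list[np.ndarray] = [pts[0]]
    out_segs: list[str] = [segs[0]]
    spans: list[tuple[int, int]] = []
    arcs: dict[int, float] = {}
    for a in range(len(pts) - 1):
        p, q = pts[a], pts[a + 1]
        routed = None
        for cyl in strand.wraps:
            res = wrap_route(p, q, cyl, tf=tfs[cyl.segment])
            if res.wrapped:
                routed = (res, cyl)
                break
        if routed is None:
            i = len(out_pts) - 1
            out_pts.append(q)
            out_segs.append(segs[a + 1])
            spans.append((i, i + 1))
        else:
            res, cyl = routed
            i = len(out_pts) - 1
            t1, t2 = res.points[1], res.points[2]
            geo = res.length - float(
                np.linalg.norm(t1 - p) + np.linalg.norm(q - t2)
            )
            out_pts.extend([t1, t2, q])
            out_segs.extend([cyl.segment, cyl.segment, segs[a + 1]])
            spans.extend([(i, i + 1), (i + 2, i + 3)])
            arcs[i + 1] = geo
    return RoutedPath(np.array(out_pts), out_segs, spans, arcs)


def path_length(points, wraps: list[WrapCylinder] | None = None) -> float:
    """Length of a polyline, with wrapped sub-paths replaced by geodesics.

    ``points`` are world coordinates; ``wraps`` (world-frame cylinders) are
    tested against every consecutive pair, first engagement wins.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two 3D points")
    total = 0.0
    for a in range(len(pts) - 1):
        p, q = pts[a], pts[a + 1]
        seg_len = float(np.linalg.norm(q - p))
        for cyl in wraps or ():
            res = wrap_route(p, q, cyl)
            if res.wrapped:
                seg_len = res.length
                break
        total += seg_len
    return total


def strand_length(
    model: LimbModel, pose: Pose, strand: MusclePath,
    euler_order: str = DEFAULT_EULER_ORDER,
) -> float:
    """Muscle-tendon path length of one strand at ``pose`` (metres)."""
    return route_strand(model, pose, strand, euler_order).length
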