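"""Rigid-segment posing, path routing and cylinder wrapping."""

import numpy as np
import pytest
from numpy.testing import assert_allclose
from scipy.optimize import minimize

import limbmoment as lm
from limbmoment.core import WrapCylinder
from limbmoment.kinematics import (
    path_length,
    path_points_world,
    route_strand,
    segment_transform,
    segment_transforms,
    transform_point,
    wrap_route,
)


def _rot(axis, deg):
    """Independent rotation-matrix oracle (explicit trigonometry)."""
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestSegmentTransforms:
    def test_neutral_pose_is_identity_everywhere(self, demo_model):
        tfs = segment_transforms(demo_model, lm.Pose.neutral())
        for seg, (R, t) in tfs.items():
            assert_allclose(R, np.eye(3), atol=1e-15)
            assert_allclose(t, 0.0, atol=1e-15)

    def test_right_hand_rotation_about_z_hinge(self, hinge_toy):
        """(0,-1,0) on the child of a Z-hinge at the origin maps to (1,0,0)."""
        pose = lm.Pose().set_angle("hinge", "fe", 90.0)
        tf = segment_transform(hinge_toy, pose, "distal")
        assert_allclose(transform_point(tf, (0, -1, 0)), (1, 0, 0), atol=1e-12)

    def test_intrinsic_xzy_composition_matches_matrix_oracle(self, demo_model):
        """aa=30, fe=40 at the hip equals Rx(30) @ Rz(40) on a probe point."""
        pose = lm.Pose().set_angle("hip", "aa", 30.0).set_angle("hip", "fe", 40.0)
        tf = segment_transform(demo_model, pose, "thigh")
        centre = demo_model.joints["hip"].centre
        probe = np.array([0.04, 0.3, -0.02])
        expected = centre + _rot("x", 30) @ _rot("z", 40) @ (probe - centre)
        assert_allclose(transform_point(tf, probe), expected, atol=1e-12)

    def test_composition_order_matters_and_matches_documented_order(self, demo_model):
        """X-then-Z differs from Z-then-X; the implementation is X-then-Z."""
        pose = lm.Pose().set_angle("hip", "aa", 30.0).set_angle("hip", "fe", 40.0)
        R, _ = segment_transform(demo_model, pose, "thigh")
        xz = _rot("x", 30) @ _rot("z", 40)
        zx = _rot("z", 40) @ _rot("x", 30)
        assert not np.allclose(xz, zx, atol=1e-6)
        assert_allclose(R, xz, atol=1e-12)

    def test_rigid_transform_preserves_pairwise_distances(self, demo_model, random_pose):
        pose = random_pose(demo_model, seed=7)
        a = np.array([0.1, 0.3, 0.05])
        b = np.array([-0.2, 0.15, -0.1])
        for seg in demo_model.segments:
            tf = segment_transform(demo_model, pose, seg)
            assert abs(
                np.linalg.norm(transform_point(tf, a) - transform_point(tf, b))
                - np.linalg.norm(a - b)
            ) < 1e-12

    def test_rigidly_attached_segment_follows_parent(self, demo_model):
        """The toes have no joint: they ride rigidly on the foot."""
        pose = lm.Pose().set_angle("ankle", "fe", 60.0)
        tfs = segment_transforms(demo_model, pose)
        assert_allclose(tfs["toes"][0], tfs["foot"][0])
        assert_allclose(tfs["toes"][1], tfs["foot"][1])

    def test_unknown_segment_raises(self, hinge_toy):
        with pytest.raises(KeyError, match="femur2"):
            segment_transform(hinge_toy, lm.Pose.neutral(), "femur2")


class TestPathPointsWorld:
    def test_neutral_pose_returns_neutral_coordinates(self, two_joint_toy):
        strand = two_joint_toy.paths[0]
        pts = path_points_world(two_joint_toy, lm.Pose.neutral(), strand)
        assert_allclose(pts, [p.location for p in strand.points], atol=1e-15)

    def test_hinge_moves_insertion_only(self, two_joint_toy):
        """Across a hinge at 90 deg the origin stays, the insertion rotates."""
        strand = two_joint_toy.paths[0]
        pose = lm.Pose().set_angle("knee", "fe", 90.0)
        pts = path_points_world(two_joint_toy, pose, strand)
        assert_allclose(pts[0], strand.points[0].location, atol=1e-15)
        assert not np.allclose(pts[1], strand.points[1].location, atol=1e-6)

    def test_via_point_rides_its_own_segment(self, demo_model, random_pose):
        """Each point moves with the rigid transform of the segment it is
        bound to (oracle: apply the transform point by point)."""
        pose = random_pose(demo_model, seed=3, lo=-30, hi=30)
        tfs = segment_transforms(demo_model, pose)
        for strand in demo_model.paths:
            pts = path_points_world(demo_model, pose, strand)
            for got, p in zip(pts, strand.points):
                assert_allclose(got, transform_point(tfs[p.segment], p.location),
                                atol=1e-12)


class TestPathLength:
    def test_collinear_points_sum_to_span(self):
        pts = [(0, 0, 0), (0.1, 0, 0), (0.3, 0, 0)]
        assert path_length(pts) == pytest.approx(0.3, abs=1e-15)

    def test_random_polyline_equals_pairwise_sum(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, size=(6, 3))
        expected = sum(np.linalg.norm(pts[i + 1] - pts[i]) for i in range(5))
        assert path_length(pts) == pytest.approx(expected, rel=1e-15)

    def test_surface_to_surface_geodesic_closed_form(self):
        """Points on a coaxial cylinder separated by arc phi and rise h
        contribute sqrt((r phi)^2 + h^2)."""
        r, phi, h = 0.05, 2.0, 0.08
        cyl = WrapCylinder("s", (0, 0, 0), (0, 0, 1), r, side=+1)
        p = np.array([r, 0.0, 0.0])
        q = np.array([r * np.cos(phi), r * np.sin(phi), h])
        res = wrap_route(p, q, cyl)
        assert res.wrapped
        assert res.length == pytest.approx(np.hypot(r * phi, h), rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            path_length([(0, 0, 0)])


def _cylinder_surface_oracle(p, q, r, side, n):
    """Shortest path past the cylinder x^2+y^2=r^2 by direct minimisation.

    The path is p -> n surface points -> q with the surface points at
    uniformly spaced angles between a free entry angle and a free arc
    span (traversed in the ``side`` sense) and independently free
    heights.  Tangency and the helical height profile are *discovered*
    by the optimiser, not assumed, so this is independent of the
    tangent-geodesic construction it checks.  The n-chord discretisation
    of the contact arc leaves an O(1/n^2) length deficit, removed by
    Richardson extrapolation at the call site.
    """
    a1 = np.arctan2(p[1], p[0])
    a2 = np.arctan2(q[1], q[0])
    dphi = (side * (a2 - a1)) % (2 * np.pi)
    frac = np.linspace(0.0, 1.0, n)

    def unpack(x):
        theta0, span = x[0], x[1]
        th = theta0 + side * span * frac
        return np.column_stack([r * np.cos(th), r * np.sin(th), x[2:]])

    def length_and_grad(x):
        theta0, span = x[0], x[1]
        th = theta0 + side * span * frac
        surf = unpack(x)
        pts = np.concatenate([[p], surf, [q]])
        diffs = np.diff(pts, axis=0)
        norms = np.linalg.norm(diffs, axis=1)
        units = diffs / norms[:, None]
        dP = units[:-1] - units[1:]  # dL/d(surface point i)
        tang = np.column_stack([-r * np.sin(th), r * np.cos(th)])
        dth = dP[:, 0] * tang[:, 0] + dP[:, 1] * tang[:, 1]
        grad = np.concatenate(
            [[np.sum(dth), side * np.sum(dth * frac)], dP[:, 2]]
        )
        return float(np.sum(norms)), grad

    def _segdist(a, b):
        """2D distance of segment ab from the origin."""
        d = b - a
        t = np.clip(-(a @ d) / (d @ d), 0.0, 1.0)
        return np.hypot(*(a + t * d))

    def violations(x):
        """Penetration depth of the two free end legs (0 when clear)."""
        surf = unpack(x)
        c1 = r - _segdist(p[:2], surf[0, :2])
        c2 = r - _segdist(q[:2], surf[-1, :2])
        return np.array([max(c1, 0.0), max(c2, 0.0)])

    x0 = np.concatenate(
        [[a1 + side * 0.3 * dphi, 0.4 * dphi],
         p[2] + (q[2] - p[2]) * np.linspace(0.2, 0.8, n)]
    )
    # quadratic penalty with continuation keeps the end legs outside the
    # cylinder; at the final weight the residual penetration is ~1e-10 m
    x = x0
    for mu in (1e3, 1e6, 1e9):

        def merit(xx, mu=mu):
            f, g = length_and_grad(xx)
            v = violations(xx)
            f += mu * float(v @ v)
            # the constraints depend on x[0] and x[1] only: cheap FD
            if v.any():
                h = 1e-7
                for i in (0, 1):
                    e = np.zeros_like(xx)
                    e[i] = h
                    vp = violations(xx + e)
                    vm = violations(xx - e)
                    g[i] += mu * float(vp @ vp - vm @ vm) / (2 * h)
            return f, g

        res = minimize(
            merit, x, jac=True, method="L-BFGS-B",
            bounds=[(None, None), (1e-6, 2 * np.pi)] + [(None, None)] * n,
            options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-14},
        )
        x = res.x
    return length_and_grad(x)[0]


class TestWrapRoute:
    def test_line_of_sight_is_straight(self):
        cyl = WrapCylinder("s", (0, 0, 0), (0, 0, 1), 0.03, side=+1)
        p, q = np.array([-0.2, 0.1, 0.0]), np.array([0.2, 0.1, 0.05])
        res = wrap_route(p, q, cyl)
        assert not res.wrapped
        assert res.length == pytest.approx(np.linalg.norm(q - p), rel=1e-15)

    def test_diametric_surface_points_give_half_circumference(self):
        r = 0.04
        cyl = WrapCylinder("s", (0, 0, 0), (0, 0, 1), r, side=+1)
        res = wrap_route((r, 0, 0), (-r, 0, 0), cyl)
        assert res.wrapped
        assert res.length == pytest.approx(np.pi * r, rel=1e-12)

    @pytest.mark.parametrize("side", [+1, -1])
    @pytest.mark.parametrize(
        "p,q",
        [
            ((-0.15, 0.01, 0.0), (0.12, -0.02, 0.06)),
            ((-0.2, 0.02, -0.03), (0.08, 0.015, 0.10)),
            ((-0.1, 0.0, 0.0), (0.1, 0.0, 0.02)),
        ],
    )
    def test_generic_route_matches_surface_minimisation_oracle(self, p, q, side):
        """Tangent-geodesic-tangent length agrees with a discretised
        shortest-path search over the cylinder surface (Richardson-
        extrapolated in the discretisation)."""
        r = 0.05
        cyl = WrapCylinder("s", (0, 0, 0), (0, 0, 1), r, side=side)
        res = wrap_route(np.array(p), np.array(q), cyl)
        assert res.wrapped
        l1 = _cylinder_surface_oracle(np.asarray(p, float), np.asarray(q, float),
                                      r, side, 24)
        l2 = _cylinder_surface_oracle(np.asarray(p, float), np.asarray(q, float),
                                      r, side, 48)
        extrapolated = l2 + (l2 - l1) / 3.0  # chord error ~ 1/n^2
        assert res.length == pytest.approx(extrapolated, abs=1e-6)

    def test_point_inside_cylinder_is_degenerate(self):
        cyl = WrapCylinder("s", (0, 0, 0), (0, 0, 1), 0.05, side=+1)
        with pytest.raises(ValueError, match="inside wrap cylinder"):
            wrap_route((0.01, 0.0, 0.0), (0.2, 0.0, 0.0), cyl)

    def test_route_length_continuous_across_engagement(self):
        """|dL| stays below 1e-6 m for 1e-4 deg steps through the angle
        where the straight segment first grazes the cylinder."""
        r = 0.03
        cyl = WrapCylinder("s", (0, 0, 0), (0, 0, 1), r, side=+1)
        p = np.array([-0.3, -0.02, 0.0])

        def L(gamma_deg):
            g = np.deg2rad(gamma_deg)
            q = np.array([0.3 * np.cos(g), 0.3 * np.sin(g), 0.04])
            return wrap_route(p, q, cyl).length

        # bracket the engagement boundary, then probe densely across it
        lo, hi = 0.0, -40.0

        def wrapped(gamma_deg):
            g = np.deg2rad(gamma_deg)
            q = np.array([0.3 * np.cos(g), 0.3 * np.sin(g), 0.04])
            return wrap_route(p, q, cyl).wrapped

        assert wrapped(lo) and not wrapped(hi)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if wrapped(mid):
                lo = mid
            else:
                hi = mid
        grid = np.arange(-50, 51) * 1e-4 + 0.5 * (lo + hi)
        lengths = np.array([L(g) for g in grid])
        assert np.max(np.abs(np.diff(lengths))) < 1e-6


class TestRouting:
    def test_coincident_points_dropped_with_warning(self, hinge_toy):
        strand = hinge_toy.paths[0]
        strand.points.insert(1, strand.points[0])
        with pytest.warns(UserWarning, match="coincident"):
            routed = route_strand(hinge_toy, lm.Pose.neutral(), strand)
        assert len(routed.points) == 4  # origin, two tangents, insertion

    def test_wrap_tangent_points_bound_to_cylinder_segment(self, hinge_toy):
        routed = route_strand(hinge_toy, lm.Pose.neutral(), hinge_toy.paths[0])
        assert routed.bound_segments == ["proximal", "distal", "distal", "distal"]
        assert len(routed.arc_lengths) == 1
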