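"""Synthetic model generators and their closed-form annotations."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

import limbmoment as lm
from limbmoment import synthetic
from limbmoment.momentarm import SweepSpec, sweep_moment_arms
from limbmoment.torque import find_sign_change, strand_torque, torque_curve


@pytest.mark.parametrize(
    "maker",
    [
        lambda: synthetic.make_hinge_toy(0.03),
        lambda: synthetic.make_hinge_toy(0.03, crossing=False),
        lambda: synthetic.make_fan_toy(1),
        lambda: synthetic.make_fan_toy(4),
        lambda: synthetic.make_via_tangent_toy(),
        lambda: synthetic.make_two_joint_toy(),
        lambda: synthetic.make_random_model(3, 6),
        lambda: synthetic.make_demo_hindlimb(),
    ],
    ids=["hinge", "hinge-noncrossing", "fan1", "fan4", "tangent", "two-joint",
         "random", "demo"],
)
def test_every_generator_passes_validation(maker):
    model = maker()
    assert lm.validate_model(model).ok
    assert model.annotations.get("synthetic") is True


class TestHingeToy:
    def test_crossing_toy_has_flat_ma_at_r(self):
        toy = synthetic.make_hinge_toy(0.05)
        curves = sweep_moment_arms(toy, SweepSpec("hinge", -50, 50, 10))
        strand = next(c for c in curves if c.kind == "strand")
        assert_allclose(strand.ma_m, 0.05, atol=1e-9)

    def test_noncrossing_toy_has_zero_ma(self):
        toy = synthetic.make_hinge_toy(0.05, crossing=False)
        curves = sweep_moment_arms(toy, SweepSpec("hinge", -50, 50, 10))
        strand = next(c for c in curves if c.kind == "strand")
        assert_allclose(strand.ma_m, 0.0, atol=0.0)

    def test_flat_torque_from_eq_product(self):
        """PCSA 1e-4 m^2 x MA 0.03 m x 3e5 N/m^2 = 0.9 Nm at every angle."""
        toy = synthetic.make_hinge_toy(0.03, pcsa_m2=1e-4)
        curves = sweep_moment_arms(toy, SweepSpec("hinge", -50, 50, 25))
        strand = next(c for c in curves if c.kind == "strand")
        tc = torque_curve(strand, fpua=3e5)
        assert_allclose(tc.torque_nm, 0.9, atol=1e-6)

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_hinge_toy(0.0)


class TestFanToy:
    def test_single_strand_degenerates_to_hinge_toy(self):
        fan = synthetic.make_fan_toy(1, r0_m=0.03)
        pose = lm.Pose.neutral()
        assert lm.muscle_moment_arm(fan, pose, "fan", "hinge") == (
            pytest.approx(0.03, abs=1e-9)
        )

    def test_symmetric_three_strand_fan_equals_middle_strand(self):
        fan = synthetic.make_fan_toy(3, spread_m=0.02, r0_m=0.05)
        pose = lm.Pose().set_angle("hinge", "fe", 15.0)
        middle = lm.moment_arm_excursion(fan, pose, fan.paths[1], "hinge")
        assert lm.muscle_moment_arm(fan, pose, "fan", "hinge") == (
            pytest.approx(middle, abs=1e-9)
        )

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_muscle_ma_is_weighted_strand_mean(self, n):
        fan = synthetic.make_fan_toy(n)
        pose = lm.Pose().set_angle("hinge", "fe", -20.0)
        strands = [lm.moment_arm_excursion(fan, pose, p, "hinge")
                   for p in fan.paths]
        fractions = [p.fraction for p in fan.paths]
        expected = float(np.dot(fractions, strands))
        assert lm.muscle_moment_arm(fan, pose, "fan", "hinge") == (
            pytest.approx(expected, rel=1e-12)
        )
        assert_allclose(strands, fan.annotations["strand_ma_m"], atol=1e-9)

    def test_zero_strands_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_fan_toy(0)


class TestTwoJointToy:
    def test_neutral_sign_matches_construction(self, two_joint_toy):
        pose = lm.Pose.neutral()
        ma = lm.moment_arm_excursion(two_joint_toy, pose,
                                     two_joint_toy.paths[0], "knee")
        assert np.sign(ma) == two_joint_toy.annotations["neutral_sign"]

    def test_sign_change_matches_planar_trig_oracle(self, two_joint_toy):
        """The swept zero crossing agrees with the closed-form collinearity
        angle to 0.1 deg."""
        curves = sweep_moment_arms(two_joint_toy, SweepSpec("knee", 0, 140, 2))
        strand = next(c for c in curves if c.kind == "strand")
        crossing = find_sign_change(strand.angles_deg, strand.ma_m)
        expected = two_joint_toy.annotations["expected_sign_change_deg"]
        assert crossing == pytest.approx(expected, abs=0.1)

    def test_origin_further_from_joint_delays_the_switch(self):
        """Moving the origin away from the knee (superiorly) shifts the
        flexor-to-extensor switch to a more flexed angle."""
        near = synthetic.make_two_joint_toy((-0.018, 0.003))
        far = synthetic.make_two_joint_toy((-0.018, 0.013))
        assert (far.annotations["expected_sign_change_deg"]
                > near.annotations["expected_sign_change_deg"])
        # and the model sweeps confirm the closed forms
        for toy in (near, far):
            curves = sweep_moment_arms(toy, SweepSpec("knee", 0, 140, 2))
            strand = next(c for c in curves if c.kind == "strand")
            got = find_sign_change(strand.angles_deg, strand.ma_m)
            assert got == pytest.approx(
                toy.annotations["expected_sign_change_deg"], abs=0.1)

    def test_hip_angle_does_not_affect_knee_ma(self, two_joint_toy):
        """The strand originates distal to the hip, so hip posture is
        irrelevant to its knee moment arm."""
        strand = two_joint_toy.paths[0]
        a = lm.moment_arm_excursion(
            two_joint_toy, lm.Pose().set_angle("knee", "fe", 30.0), strand, "knee")
        pose = lm.Pose().set_angle("knee", "fe", 30.0).set_angle("hip", "fe", 40.0)
        b = lm.moment_arm_excursion(two_joint_toy, pose, strand, "knee")
        assert a == pytest.approx(b, abs=1e-12)


class TestRandomModel:
    def test_same_seed_reproduces_identical_model(self):
        a = synthetic.make_random_model(7, 5)
        b = synthetic.make_random_model(7, 5)
        assert [p.fraction for p in a.paths] == [p.fraction for p in b.paths]
        for pa, pb in zip(a.paths, b.paths):
            for xa, xb in zip(pa.points, pb.points):
                assert_allclose(xa.location, xb.location)

    def test_different_seeds_differ(self):
        a = synthetic.make_random_model(1, 5)
        b = synthetic.make_random_model(2, 5)
        assert not np.allclose(a.paths[0].points[0].location,
                               b.paths[0].points[0].location)


class TestDemoHindlimb:
    def test_gorilla_scale_dimensions(self, demo_model):
        assert demo_model.bone_lengths_m["femur"] == pytest.approx(0.271)
        assert demo_model.bone_lengths_m["tibia"] == pytest.approx(0.226)
        hip = demo_model.joints["hip"].centre
        knee = demo_model.joints["knee"].centre
        # neutral posture: hip directly above the knee
        assert hip[0] == knee[0] == 0.0
        assert np.linalg.norm(hip - knee) == pytest.approx(0.271)

    def test_every_muscle_has_architecture(self, demo_model):
        for muscle in demo_model.muscles():
            assert muscle in demo_model.architecture

    def test_gastrocnemius_switch_matches_planar_annotation(self, demo_model):
        curves = sweep_moment_arms(demo_model, SweepSpec("knee", 0, 140, 2))
        gast = next(c for c in curves
                    if c.kind == "muscle" and c.entity == "gastrocnemius")
        got = find_sign_change(gast.angles_deg, gast.ma_m)
        assert got == pytest.approx(
            demo_model.annotations["gastrocnemius_knee_sign_change_deg"], abs=0.1)
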