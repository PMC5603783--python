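import numpy as np
import pytest

import limbmoment as lm
from limbmoment import synthetic


@pytest.fixture
def hinge_toy():
    return synthetic.make_hinge_toy(0.03)


@pytest.fixture
def noncrossing_toy():
    return synthetic.make_hinge_toy(0.03, crossing=False)


@pytest.fixture
def fan_toy():
    return synthetic.make_fan_toy(3)


@pytest.fixture
def two_joint_toy():
    return synthetic.make_two_joint_toy()


@pytest.fixture
def via_tangent_toy():
    return synthetic.make_via_tangent_toy(0.03)


@pytest.fixture(scope="session")
def demo_model():
    return synthetic.make_demo_hindlimb()


@pytest.fixture
def random_pose():
    """Factory for reproducible random poses over a model's joints."""

    def make(model, seed, lo=-40.0, hi=40.0):
        rng = np.random.default_rng(seed)
        pose = lm.Pose(allow_out_of_range=True)
        for j in model.joints:
            for ax in ("fe", "aa", "la"):
                pose.set_angle(j, ax, float(rng.uniform(lo, hi)))
        return pose

    return make
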