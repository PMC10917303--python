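import numpy as np
import pytest

from morphsim import Morphology, build_desk_model, build_full_structural_model
from morphsim.geometry import AnalyticGeometry
from morphsim.kinematics import PlanarKinematics
from morphsim.model import (
    JointSpec,
    MusclePath,
    MuscleSpec,
    MusculoskeletalModel,
    SegmentSpec,
    apply_segment_scaling,
)


@pytest.fixture(scope="session")
def desk_model():
    return build_desk_model()


@pytest.fixture(scope="session")
def full_model():
    return build_full_structural_model()


@pytest.fixture(scope="session")
def desk_geo(desk_model):
    return AnalyticGeometry(desk_model)


@pytest.fixture(scope="session")
def desk_kin(desk_model):
    return PlanarKinematics(desk_model)


@pytest.fixture()
def generic(desk_model):
    return Morphology.generic(desk_model)


@pytest.fixture(scope="session")
def pendulum():
    """Point-mass pendulum: massless base on the root joint, 2 kg bob on
    a 1 m massless rod; closed forms M = m l^2, |G| = m g l."""
    segs = [
        SegmentSpec("base", None, (0.1, 0.1, 0.1), 1e-9, (0, 0), (0, 0, 1e-12), "base"),
        SegmentSpec("rod", "pin", (0.1, 1.0, 0.1), 2.0, (0.0, -0.5), (0, 0, 0.0), "rod"),
    ]
    joints = [
        JointSpec("root", "planar-free", None, "base", (0, 0), ["rx", "ry", "rp"],
                  [(-1, 1)] * 3),
        JointSpec("pin", "revolute", "base", "rod", (0, 0), ["th"], [(-7, 7)]),
    ]
    m = MusculoskeletalModel("pendulum", segs, joints, [], [], stature_segments=["rod"])
    m.validate()
    return m


@pytest.fixture(scope="session")
def two_link_muscle_model():
    """Two collinear segments with one straight-line muscle along the
    y-axis, for affine-scaling and straight-path oracles."""
    segs = [
        SegmentSpec("base", None, (0.1, 0.5, 0.1), 1.0, (0, -0.25), (0, 0, 0.01), "base"),
        SegmentSpec("rod", "pin", (0.1, 0.4, 0.1), 1.0, (0, -0.2), (0, 0, 0.01), "rod"),
    ]
    joints = [
        JointSpec("root", "planar-free", None, "base", (0, 0), ["rx", "ry", "rp"],
                  [(-1, 1)] * 3),
        JointSpec("pin", "revolute", "base", "rod", (0.0, -0.5), ["th"], [(-2, 2)]),
    ]
    muscles = [
        MuscleSpec(
            name="line", spanned_coordinates=["th"], pcsa=1e-3, sigma=6e5,
            l_t_slack=0.2, l_m_opt=0.1, alpha_m=0.1,
            path=MusclePath(kind="via", points=[("base", (0.0, -0.1)), ("rod", (0.0, -0.2))]),
        )
    ]
    m = MusculoskeletalModel("two-link", segs, joints, muscles, [],
                             stature_segments=["base", "rod"])
    m.validate()
    return m
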