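"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import copy

import numpy as np
import pytest

import caninegait as cg
from caninegait.model import BodySegment, JointDefinition, MusculoskeletalModel
from caninegait.muscles import MuscleParameters


@pytest.fixture(scope="session")
def noise_free_spec() -> cg.SyntheticGaitSpec:
    return cg.SyntheticGaitSpec(seed=1, marker_noise_mm=0.0)


@pytest.fixture(scope="session")
def gait_model(noise_free_spec):
    model, tissue = cg.generate_morphology(noise_free_spec)
    return model, tissue


@pytest.fixture(scope="session")
def noise_free_trial(noise_free_spec, gait_model):
    model, _ = gait_model
    return cg.generate_trial(noise_free_spec, model)


@pytest.fixture(scope="session")
def consistent_trial(gait_model):
    """Trial whose plate wrenches exactly balance the kinematics."""
    spec = cg.SyntheticGaitSpec(seed=1, marker_noise_mm=0.0, dynamically_consistent_grf=True)
    model, _ = cg.generate_morphology(spec)
    return cg.generate_trial(spec, model)


@pytest.fixture()
def model_copy(gait_model):
    """Function-scoped deep copy for tests that mutate the model."""
    model, _ = gait_model
    return copy.deepcopy(model)


def make_pendulum(mass: float = 0.5, length: float = 0.2) -> MusculoskeletalModel:
    """Point-mass pendulum hanging from a hinge on a (held) base segment."""
    segs = {
        "base": BodySegment("base", 1.0, np.zeros(3), np.eye(3) * 1e-6),
        "rod": BodySegment("rod", mass, np.array([0.0, -length, 0.0]), np.eye(3) * 1e-12),
    }
    joints = [
        JointDefinition("root", "free", None, "base", np.zeros(3)),
        JointDefinition("pin", "hinge", "base", "rod", np.zeros(3)),
    ]
    return MusculoskeletalModel(segs, joints)


def make_hinge_with_muscles(paths, insert_radius: float = 0.02) -> MusculoskeletalModel:
    """Base + one hinged link with muscles given as (name, origin, insertion)
    point pairs; origin on the base, insertion on the link."""
    segs = {
        "base": BodySegment("base", 1.0, np.zeros(3), np.eye(3) * 1e-6),
        "link": BodySegment("link", 0.2, np.array([0.0, -0.1, 0.0]), np.eye(3) * 1e-7),
    }
    joints = [
        JointDefinition("root", "free", None, "base", np.zeros(3)),
        JointDefinition("hinge", "hinge", "base", "link", np.zeros(3)),
    ]
    muscles = []
    for name, vol, pen, fib, tsl, origin, insertion in paths:
        muscles.append(
            MuscleParameters(
                name, vol, pen, fib, tsl,
                path=[("base", np.asarray(origin, float)), ("link", np.asarray(insertion, float))],
            )
        )
    return MusculoskeletalModel(segs, joints, muscles=muscles)


@pytest.fixture(scope="session")
def pendulum_model():
    return make_pendulum()
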