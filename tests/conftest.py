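"""Shared fixtures: courses, meshes and simulated runs.

Expensive artifacts (full-course balanced runs) are session-scoped; most
module tests use a shorter 5-gate course to keep the suite fast.
"""

import numpy as np
import pytest

from skipose.simulate import CourseSpec, SkierSpec, make_course, make_run
from skipose.terrain import SlopeMesh


@pytest.fixture(scope="session")
def default_course():
    return CourseSpec()


@pytest.fixture(scope="session")
def default_world(default_course):
    mesh, gates = make_course(default_course)
    return mesh, gates


@pytest.fixture(scope="session")
def default_skier():
    return SkierSpec()


@pytest.fixture(scope="session")
def balanced_run(default_world, default_skier):
    return make_run(default_world, default_skier)


@pytest.fixture(scope="session")
def short_course():
    return CourseSpec(length_m=120.0, drop_m=34.0, n_gates=5)


@pytest.fixture(scope="session")
def short_world(short_course):
    mesh, gates = make_course(short_course)
    return mesh, gates


@pytest.fixture(scope="session")
def short_run(short_course, default_skier):
    return make_run(short_course, default_skier)


@pytest.fixture
def flat_mesh():
    """10x10 m flat mesh at z = 0."""
    return SlopeMesh(-5.0, -5.0, 1.0, 1.0, np.zeros((11, 11)))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
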