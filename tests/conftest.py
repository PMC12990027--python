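import numpy as np
import pytest

from jawmotion import (
    ExcursionParams,
    TriangleMesh,
    build_trajectory,
    estimate_pose_set,
    generate_arch_mesh,
    generate_pose_records,
)


def make_cube() -> TriangleMesh:
    """Unit cube: 8 vertices, 12 facets."""
    vertices = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    facets = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x = 0
            [4, 6, 7], [4, 7, 5],  # x = 1
            [0, 4, 5], [0, 5, 1],  # y = 0
            [2, 3, 7], [2, 7, 6],  # y = 1
            [0, 2, 6], [0, 6, 4],  # z = 0
            [1, 5, 7], [1, 7, 3],  # z = 1
        ]
    )
    return TriangleMesh(vertices=vertices, facets=facets)


@pytest.fixture(scope="session")
def arch():
    return generate_arch_mesh(n_vertices=500, seed=1)


@pytest.fixture(scope="session")
def noiseless_records(arch):
    return generate_pose_records(arch, ExcursionParams(seed=1))


@pytest.fixture(scope="session")
def pose_set(noiseless_records):
    records, _ = noiseless_records
    return estimate_pose_set(records)


@pytest.fixture(scope="session")
def default_trajectory(pose_set):
    return build_trajectory(pose_set)


@pytest.fixture
def cube():
    return make_cube()
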