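import numpy as np
import pytest

from voxmesh import fixtures
from voxmesh.mesh_core import SurfaceMesh


@pytest.fixture
def icosphere():
    return fixtures.make_icosphere(1.0, 2)


@pytest.fixture
def icosphere_fine():
    return fixtures.make_icosphere(1.0, 3)


@pytest.fixture
def torus():
    return fixtures.make_torus(2.0, 0.6, 32, 16)


@pytest.fixture
def unit_cube():
    return fixtures.make_box((1.0, 1.0, 1.0), center=(0.5, 0.5, 0.5))


@pytest.fixture
def single_triangle():
    return SurfaceMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
                       np.array([[0, 1, 2]]))


def random_small_mesh(rng: np.random.Generator, n_tris: int = 8) -> SurfaceMesh:
    """Random triangle soup inside the unit cube (for oracle-equality tests)."""
    verts = rng.random((3 * n_tris, 3))
    tris = np.arange(3 * n_tris).reshape(-1, 3)
    return SurfaceMesh(verts, tris)
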