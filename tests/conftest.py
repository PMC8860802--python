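import numpy as np
import pytest

from blebpoint import SyntheticSpec, make_dome_mesh, make_fields
from blebpoint.mesh_io import SurfaceMesh


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def dome_case(default_spec):
    """Default synthetic dome-on-tube mesh with ground-truth labels."""
    return make_dome_mesh(default_spec)


@pytest.fixture(scope="session")
def dome_fields(default_spec, dome_case):
    mesh, truth = dome_case
    return make_fields(mesh, truth, default_spec, seed=0)


@pytest.fixture
def flat_patch():
    """10 mm x 10 mm planar patch of two triangles in the z=0 plane."""
    v = np.array(
        [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], dtype=float
    )
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceMesh(v, f)


def grid_mesh(n: int = 21, size: float = 10.0) -> SurfaceMesh:
    """Regularly triangulated planar grid (interior vertices for FEM tests)."""
    xs = np.linspace(0, size, n)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return SurfaceMesh(verts, np.array(faces))


@pytest.fixture
def planar_grid():
    return grid_mesh()
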