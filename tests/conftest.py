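import numpy as np
import pytest
import trimesh

from casm.mesh import TriangleMesh
from casm.synthetic import make_canonical_patch


@pytest.fixture(scope="session")
def icosphere():
    """Unit icosphere (subdivision 3), closed surface."""
    s = trimesh.creation.icosphere(3, radius=1.0)
    return TriangleMesh(s.vertices, s.faces)


@pytest.fixture(scope="session")
def femur_patch():
    return make_canonical_patch("femur", 1000, seed=11)


@pytest.fixture(scope="session")
def tibia_patch():
    return make_canonical_patch("medial_tibia", 600, seed=11)


@pytest.fixture(scope="session")
def flat_grid():
    """Unit-square grid (11 x 11 vertices) triangulated in the plane z=0."""
    n = 11
    xs = np.linspace(0, 1, n)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return TriangleMesh(verts, np.array(faces))


def dense_flat_grid(n: int, extent: float = 1.0) -> TriangleMesh:
    xs = np.linspace(0, extent, n)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return TriangleMesh(verts, np.array(faces))
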