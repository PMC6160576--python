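import numpy as np
import pytest

from ecgforward import TriSurfaceMesh, make_icosphere, make_scene


@pytest.fixture
def tetrahedron() -> TriSurfaceMesh:
    """Regular tetrahedron, outward-oriented (the smallest closed mesh)."""
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    tris = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    mesh = TriSurfaceMesh(verts, tris)
    mesh.validate(require_closed=True)
    return mesh


@pytest.fixture(scope="session")
def icosphere2() -> TriSurfaceMesh:
    return make_icosphere(1.0, 2)


@pytest.fixture(scope="session")
def default_scene():
    return make_scene("sock_like", 500, 770)


def clipped_icosphere(subdivisions: int = 2, z_cut: float = 0.0) -> TriSurfaceMesh:
    """Icosphere with all triangles whose centroid is above z_cut removed."""
    ico = make_icosphere(1.0, subdivisions)
    keep = ico.vertices[ico.triangles].mean(axis=1)[:, 2] <= z_cut
    tris = ico.triangles[keep]
    used = np.unique(tris)
    remap = -np.ones(ico.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriSurfaceMesh(ico.vertices[used], remap[tris])


def planar_grid(nx: int = 9, ny: int = 9) -> TriSurfaceMesh:
    """Right-triangulated unit-square grid in the z=0 plane."""
    xs, ys = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny), indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            tris.append([a, b, a + 1])
            tris.append([b, b + 1, a + 1])
    return TriSurfaceMesh(verts, np.array(tris))


def grid_boundary(nx: int = 9, ny: int = 9) -> np.ndarray:
    idx = np.arange(nx * ny).reshape(nx, ny)
    return np.unique(
        np.concatenate([idx[0], idx[-1], idx[:, 0], idx[:, -1]])
    )
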