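import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgforward import (
    MeshError,
    MeshFormatError,
    MeshTopologyError,
    TriSurfaceMesh,
    boundary_loops,
    cap_open_mesh,
    fit_ellipsoid,
    load_mesh,
    make_icosphere,
    save_mesh,
)

from conftest import clipped_icosphere


# ------------------------------------------------------------------ validation


def test_tetrahedron_is_closed(tetrahedron):
    assert tetrahedron.euler_characteristic() == 2
    assert tetrahedron.is_closed()


def test_out_of_range_index_rejected():
    with pytest.raises(MeshError, match="out of range"):
        TriSurfaceMesh(np.eye(3), [[0, 1, 3]]).validate()


def test_repeated_vertex_rejected():
    with pytest.raises(MeshError, match="repeats"):
        TriSurfaceMesh(np.eye(3), [[0, 1, 1]]).validate()


def test_zero_area_triangle_rejected():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
    with pytest.raises(MeshError, match="zero-area"):
        TriSurfaceMesh(verts, [[0, 1, 2]]).validate()


def test_inconsistent_orientation_rejected(tetrahedron):
    tris = tetrahedron.triangles.copy()
    tris[0] = tris[0][::-1]
    with pytest.raises(MeshTopologyError, match="orientation"):
        TriSurfaceMesh(tetrahedron.vertices, tris).validate()


def test_open_mesh_fails_closed_validation(tetrahedron):
    open_mesh = TriSurfaceMesh(tetrahedron.vertices, tetrahedron.triangles[:3])
    with pytest.raises(MeshTopologyError, match="boundary"):
        open_mesh.validate(require_closed=True)


# ------------------------------------------------------------------------- I/O


def test_ptsfac_tetrahedron_roundtrip(tetrahedron, tmp_path):
    save_mesh(tetrahedron, tmp_path / "tet.pts")
    # on-disk .fac indices are 1-based
    first = (tmp_path / "tet.fac").read_text().splitlines()[0].split()
    assert min(int(v) for v in first) >= 1
    mesh = load_mesh(tmp_path / "tet.pts")
    assert mesh.n_vertices == 4 and mesh.n_triangles == 4
    assert mesh.euler_characteristic() == 2
    np.testing.assert_allclose(mesh.vertices, tetrahedron.vertices, atol=1e-8)
    np.testing.assert_array_equal(mesh.triangles, tetrahedron.triangles)


def test_ptsfac_out_of_range_index(tmp_path):
    (tmp_path / "m.pts").write_text("0 0 0\n1 0 0\n0 1 0\n0 0 1\n")
    (tmp_path / "m.fac").write_text("1 2 3\n1 2 5\n")
    with pytest.raises(MeshFormatError, match="index out of range"):
        load_mesh(tmp_path / "m.pts")


def test_off_roundtrip_icosphere(icosphere2, tmp_path):
    save_mesh(icosphere2, tmp_path / "s.off")
    mesh = load_mesh(tmp_path / "s.off")
    assert np.abs(mesh.vertices - icosphere2.vertices).max() < 1e-8
    np.testing.assert_array_equal(mesh.triangles, icosphere2.triangles)


def test_labels_roundtrip(tetrahedron, tmp_path):
    tetrahedron.region_labels = np.array(
        ["ventricular", "atrial", "cap", "unlabeled"], dtype=object
    )
    save_mesh(tetrahedron, tmp_path / "t.pts")
    mesh = load_mesh(tmp_path / "t.pts")
    assert list(mesh.region_labels) == list(tetrahedron.region_labels)


def test_save_empty_mesh_errors(tmp_path):
    empty = TriSurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    with pytest.raises(MeshError, match="empty"):
        save_mesh(empty, tmp_path / "e.off")


def test_parse_error_names_line(tmp_path):
    (tmp_path / "bad.pts").write_text("0 0 0\n1 0\n")
    (tmp_path / "bad.fac").write_text("1 1 1\n")
    with pytest.raises(MeshFormatError, match="bad.pts:2"):
        load_mesh(tmp_path / "bad.pts")


@settings(max_examples=20, deadline=None)
@given(
    fmt=st.sampled_from(["ptsfac", "off", "ply"]),
    seed=st.integers(0, 10_000),
)
def test_roundtrip_property_random_meshes(fmt, seed, tmp_path_factory):
    """load(save(mesh)) preserves connectivity and labels for all formats."""
    rng = np.random.default_rng(seed)
    base = make_icosphere(1.0, 1)
    verts = base.vertices * (1.0 + 0.2 * rng.standard_normal((base.n_vertices, 1)))
    labels = rng.choice(["ventricular", "atrial", "cap"], base.n_vertices).astype(object)
    mesh = TriSurfaceMesh(verts, base.triangles, labels)
    path = tmp_path_factory.mktemp("rt") / {"ptsfac": "m.pts", "off": "m.off", "ply": "m.ply"}[fmt]
    save_mesh(mesh, path, format=fmt)
    back = load_mesh(path, format=fmt)
    np.testing.assert_array_equal(back.triangles, mesh.triangles)
    assert np.abs(back.vertices - mesh.vertices).max() < 1e-7
    assert list(back.region_labels) == list(mesh.region_labels)


# -------------------------------------------------------------- boundary loops


def test_closed_mesh_has_no_loops(icosphere2):
    assert boundary_loops(icosphere2) == []


def test_clipped_icosphere_single_loop():
    mesh = clipped_icosphere(2, z_cut=0.0)
    loops = boundary_loops(mesh)
    assert len(loops) == 1
    # oracle: brute-force census of edges used exactly once
    de = mesh.directed_edges()
    ue = np.sort(de, axis=1)
    uniq, counts = np.unique(ue, axis=0, return_counts=True)
    n_boundary_edges = int((counts == 1).sum())
    assert len(loops[0]) == n_boundary_edges
    # loop vertices hug the cut plane (within one edge length)
    edge_len = np.linalg.norm(
        mesh.vertices[uniq[:, 0]] - mesh.vertices[uniq[:, 1]], axis=1
    ).max()
    assert np.abs(mesh.vertices[loops[0].vertices][:, 2]).max() <= edge_len


def test_two_holes_two_loops():
    ico = make_icosphere(1.0, 2)
    cz = ico.vertices[ico.triangles].mean(axis=1)[:, 2]
    keep = (cz < 0.8) & (cz > -0.8)  # cut both poles
    tris = ico.triangles[keep]
    used = np.unique(tris)
    remap = -np.ones(ico.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = TriSurfaceMesh(ico.vertices[used], remap[tris])
    loops = boundary_loops(mesh)
    assert len(loops) == 2
    de = mesh.directed_edges()
    _, counts = np.unique(np.sort(de, axis=1), axis=0, return_counts=True)
    assert sum(len(l) for l in loops) == int((counts == 1).sum())


def test_loop_consecutive_vertices_share_edges():
    mesh = clipped_icosphere(2)
    loop = boundary_loops(mesh)[0].vertices
    edges = {tuple(sorted(e)) for e in mesh.undirected_edges().tolist()}
    for a, b in zip(loop, np.roll(loop, -1)):
        assert tuple(sorted((int(a), int(b)))) in edges


# --------------------------------------------------------------- ellipsoid fit


def test_fit_ellipsoid_recovers_axes():
    rng = np.random.default_rng(0)
    u = rng.standard_normal((400, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * np.array([3.0, 2.0, 1.0]) + np.array([1.0, -2.0, 0.5])
    center, rot, radii = fit_ellipsoid(pts)
    np.testing.assert_allclose(center, [1.0, -2.0, 0.5], atol=1e-8)
    np.testing.assert_allclose(sorted(radii), [1.0, 2.0, 3.0], atol=1e-8)


def test_fit_degenerate_ring_falls_back_to_sphere():
    t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    ring = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    center, rot, radii = fit_ellipsoid(ring)
    assert np.all(radii > 0)


# ------------------------------------------------------------------------- cap


def test_cap_hemisphere_recovers_sphere():
    mesh = clipped_icosphere(2, z_cut=0.0)
    closed = cap_open_mesh(mesh, cap_resolution=3)
    closed.validate(require_closed=True)
    assert closed.euler_characteristic() == 2
    cap_idx = np.flatnonzero(closed.region_labels == "cap")
    assert len(cap_idx) > 0
    r = np.linalg.norm(closed.vertices[cap_idx], axis=1)
    assert np.abs(r - 1.0).max() < 0.05  # on the unit sphere within 5%


def test_cap_on_closed_mesh_errors(icosphere2):
    with pytest.raises(MeshError, match="exactly 1 boundary loop"):
        cap_open_mesh(icosphere2, cap_resolution=2)


def test_capped_mesh_has_no_boundary():
    closed = cap_open_mesh(clipped_icosphere(2), cap_resolution=2)
    assert boundary_loops(closed) == []


@pytest.mark.parametrize("resolution", [1, 2, 4])
def test_cap_resolutions_all_close(resolution):
    closed = cap_open_mesh(clipped_icosphere(2), cap_resolution=resolution)
    closed.validate(require_closed=True)
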