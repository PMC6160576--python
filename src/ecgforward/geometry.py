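"""Analytic triangle integrals shared by the forward solver and scene checks."""

from __future__ import annotations

import numpy as np

from .mesh import TriSurfaceMesh

_CHUNK = 256  # field points per vectorized block; bounds peak memory


def triangle_solid_angles(
    points: np.ndarray, mesh: TriSurfaceMesh, out: np.ndarray | None = None
) -> np.ndarray:
    """Signed solid angle of every triangle seen from every field point.

    Uses the van Oosterom-Strackee arctangent formula (exact for planar
    triangles).  Sign convention: a closed outward-oriented surface sums to
    +4*pi for interior points and 0 for exterior points.  Shape:
    (n_points, n_triangles).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.vertices[mesh.triangles]  # (F, 3, 3)
    n_p, n_f = len(pts), len(tri)
    if out is None:
        out = np.empty((n_p, n_f))
    t1, t2, t3 = tri[:, 0], tri[:, 1], tri[:, 2]
    for lo in range(0, n_p, _CHUNK):
        hi = min(lo + _CHUNK, n_p)
        p = pts[lo:hi, None, :]
        r1 = t1[None] - p
        r2 = t2[None] - p
        r3 = t3[None] - p
        l1 = np.sqrt(np.einsum("cfi,cfi->cf", r1, r1))
        l2 = np.sqrt(np.einsum("cfi,cfi->cf", r2, r2))
        l3 = np.sqrt(np.einsum("cfi,cfi->cf", r3, r3))
        num = np.einsum("cfi,cfi->cf", r1, np.cross(r2, r3))
        den = l1 * l2 * l3
        den += np.einsum("cfi,cfi->cf", r1, r2) * l3
        den += np.einsum("cfi,cfi->cf", r2, r3) * l1
        den += np.einsum("cfi,cfi->cf", r3, r1) * l2
        out[lo:hi] = 2.0 * np.arctan2(num, den)
    return out


def triangle_inv_distance_integrals(
    points: np.ndarray, mesh: TriSurfaceMesh
) -> np.ndarray:
    """Exact single-layer integrals I(x) = integral over T of dA / |x - y|.

    Closed-form edge-sum expression for a constant density on a planar
    triangle; valid for field points anywhere, including on the triangle
    (vertex-singular integrals are finite and handled by the t -> 0 limit).
    Shape: (n_points, n_triangles).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.vertices[mesh.triangles]  # (F, 3, 3)
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)  # (F, 3)
    scale = np.sqrt(mesh.triangle_areas())  # per-triangle length scale
    n_p, n_f = len(pts), len(tri)
    out = np.empty((n_p, n_f))
    omega = triangle_solid_angles(pts, mesh)
    for lo in range(0, n_p, _CHUNK):
        hi = min(lo + _CHUNK, n_p)
        x = pts[lo:hi, None, :]  # (c, 1, 3)
        d = np.einsum("cfi,fi->cf", x - tri[None, :, 0, :], nrm)  # signed height
        acc = np.zeros((hi - lo, n_f))
        for e in range(3):
            p, q = tri[:, e], tri[:, (e + 1) % 3]
            ln = np.linalg.norm(q - p, axis=1, keepdims=True)
            ehat = (q - p) / ln
            uhat = np.cross(ehat, nrm)  # in-plane outward edge normal
            rho = x - d[:, :, None] * nrm[None, :, :]  # projection onto plane
            t = np.einsum("cfi,fi->cf", p[None] - rho, uhat)
            s_m = np.einsum("cfi,fi->cf", p[None] - rho, ehat)
            s_p = np.einsum("cfi,fi->cf", q[None] - rho, ehat)
            R_m = np.linalg.norm(x - p[None], axis=-1)
            R_p = np.linalg.norm(x - q[None], axis=-1)
            num = R_p + s_p
            den = R_m + s_m
            tiny = 1e-12 * scale[None, :]
            ok = (np.abs(t) > tiny) & (num > tiny) & (den > tiny)
            term = np.zeros_like(t)
            term[ok] = t[ok] * np.log(num[ok] / den[ok])
            acc += term
        out[lo:hi] = acc - np.abs(d) * np.abs(omega[lo:hi])
    return out


def lumping_matrix(mesh: TriSurfaceMesh):
    """Sparse (n_triangles x n_vertices) operator assigning 1/3 per vertex."""
    from scipy import sparse

    F = mesh.n_triangles
    rows = np.repeat(np.arange(F), 3)
    cols = mesh.triangles.ravel()
    vals = np.full(3 * F, 1.0 / 3.0)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(F, mesh.n_vertices))


def double_layer_matrix(points: np.ndarray, mesh: TriSurfaceMesh) -> np.ndarray:
    """Vertex-lumped solid-angle matrix W, shape (n_points, n_vertices).

    Row sums equal the total solid angle of the surface from each point
    exactly (lumping preserves triangle totals).
    """
    S = lumping_matrix(mesh)
    per_tri = triangle_solid_angles(points, mesh)
    return (S.T @ per_tri.T).T


def single_layer_matrix(points: np.ndarray, mesh: TriSurfaceMesh) -> np.ndarray:
    """Vertex-lumped single-layer matrix of 1/R integrals."""
    S = lumping_matrix(mesh)
    per_tri = triangle_inv_distance_integrals(points, mesh)
    return (S.T @ per_tri.T).T


def points_inside_mesh(points: np.ndarray, mesh: TriSurfaceMesh) -> np.ndarray:
    """Winding-number containment test against a closed oriented surface."""
    omega = triangle_solid_angles(points, mesh)
    return omega.sum(axis=1) / (4.0 * np.pi) > 0.5
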