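"""Laplacian interpolation of partially sampled potentials on a triangle mesh.

Unknown node values solve  L_uu phi_u = -L_uk phi_k  for a symmetric surface
Laplacian L with zero row sums.  Two weight schemes are provided: cotangent
(linear precision on planar meshes; weights may be negative on obtuse
triangulations) and inverse_distance (strictly positive weights, hence a
discrete maximum principle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .mesh import TriSurfaceMesh

_SCHEMES = ("cotangent", "inverse_distance")


class InterpolationError(Exception):
    pass


@dataclass
class SurfaceLaplacian:
    """Sparse symmetric operator with zero row sums over mesh vertices."""

    matrix: sparse.csr_matrix
    scheme: str
    mesh_id: str
    degenerate_triangles: int = 0  # cotangent fallbacks recorded, not fatal

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]


def build_laplacian(mesh: TriSurfaceMesh, scheme: str = "cotangent") -> SurfaceLaplacian:
    """Assemble the surface Laplacian; open meshes are allowed.

    Convention: off-diagonal entries are +w_ij on mesh edges, diagonals make
    every row sum to zero (so L applied to a constant vanishes).
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {_SCHEMES}")
    mesh.validate()
    n = mesh.n_vertices
    tris = mesh.triangles
    V = mesh.vertices
    degenerate = 0

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    if scheme == "inverse_distance":
        edges = mesh.undirected_edges()
        d = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)
        w = 1.0 / d
        rows = [edges[:, 0], edges[:, 1]]
        cols = [edges[:, 1], edges[:, 0]]
        vals = [w, w]
    else:
        areas = mesh.triangle_areas()
        bad = areas < 1e-10
        degenerate = int(bad.sum())
        for k in range(3):
            i = tris[:, k]
            j = tris[:, (k + 1) % 3]
            o = tris[:, (k + 2) % 3]  # vertex opposite edge (i, j)
            u = V[i] - V[o]
            v = V[j] - V[o]
            cos = np.einsum("ij,ij->i", u, v)
            sin = np.linalg.norm(np.cross(u, v), axis=1)
            w = 0.5 * cos / np.maximum(sin, 1e-300)
            # degenerate triangle: fall back to inverse-distance for its edges
            d = np.linalg.norm(V[i] - V[j], axis=1)
            w = np.where(bad, 1.0 / np.maximum(d, 1e-300), w)
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
    L = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    L = L - sparse.diags(np.asarray(L.sum(axis=1)).ravel())
    return SurfaceLaplacian(
        matrix=L.tocsr(),
        scheme=scheme,
        mesh_id=mesh.mesh_id(),
        degenerate_triangles=degenerate,
    )


class _FactoredInterpolator:
    """L_uu factored once for a fixed sampling mask, reused across frames."""

    def __init__(self, laplacian: SurfaceLaplacian, known_idx: np.ndarray):
        n = laplacian.n_vertices
        known_idx = np.asarray(known_idx, dtype=np.int64)
        if len(known_idx) == 0:
            raise InterpolationError("known index set is empty")
        if len(np.unique(known_idx)) != len(known_idx):
            raise InterpolationError("known index set contains duplicates")
        if known_idx.min() < 0 or known_idx.max() >= n:
            raise InterpolationError("known index out of range")
        self.n = n
        self.known = known_idx
        mask = np.zeros(n, dtype=bool)
        mask[known_idx] = True
        self.unknown = np.flatnonzero(~mask)
        L = laplacian.matrix
        if len(self.unknown):
            L_uu = L[self.unknown][:, self.unknown].tocsc()
            self._check_connectivity(L, L_uu)
            self.L_uk = L[self.unknown][:, self.known].tocsr()
            self.lu = splu(L_uu)
        else:
            self.lu = None

    def _check_connectivity(self, L, L_uu) -> None:
        ncomp, labels = csgraph.connected_components(abs(L_uu), directed=False)
        if ncomp <= 1 and len(self.unknown) and self._touches_known(L, self.unknown):
            return
        for c in range(ncomp):
            comp = self.unknown[labels == c]
            if not self._touches_known(L, comp):
                raise InterpolationError(
                    f"unknown component of {len(comp)} nodes (e.g. node "
                    f"{int(comp[0])}) has no known neighbor; system singular"
                )

    def _touches_known(self, L, comp: np.ndarray) -> bool:
        sub = L[comp][:, self.known]
        return sub.count_nonzero() > 0

    def __call__(self, known_vals: np.ndarray) -> np.ndarray:
        known_vals = np.asarray(known_vals, dtype=float)
        single = known_vals.ndim == 1
        kv = known_vals.reshape(len(self.known), -1)
        out = np.empty((self.n, kv.shape[1]))
        out[self.known] = kv
        if self.lu is not None:
            out[self.unknown] = self.lu.solve(-(self.L_uk @ kv))
        return out[:, 0] if single else out


def interpolate(
    laplacian: SurfaceLaplacian, known_idx: np.ndarray, known_vals: np.ndarray
) -> np.ndarray:
    """Fill a full per-vertex vector (or node x frame matrix) from samples.

    ``known_vals`` rows correspond one-to-one with ``known_idx`` (any order,
    no duplicates).  Returned values equal ``known_vals`` exactly at known
    nodes.
    """
    return _FactoredInterpolator(laplacian, known_idx)(known_vals)


def make_interpolator(laplacian: SurfaceLaplacian, known_idx: np.ndarray):
    """Factor once per sampling mask; call with per-frame known values."""
    return _FactoredInterpolator(laplacian, known_idx)
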