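"""Triangle surface meshes: data model, validation, text I/O, boundary loops,
and ellipsoidal-cap closure of open (sock-like) surfaces.

Coordinates are millimetres throughout.  Triangle indices are 0-based in
memory; the ``.pts``/``.fac`` dialect is 1-based on disk and converted on
load/save.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

REGION_LABELS = ("ventricular", "atrial", "cap", "torso", "unlabeled")

_MIN_TRIANGLE_AREA = 1e-12  # mm^2


class MeshError(Exception):
    """Base class for mesh problems."""


class MeshFormatError(MeshError):
    """A file could not be parsed in the requested dialect."""


class MeshTopologyError(MeshError):
    """Connectivity violates a mesh invariant (non-manifold, open, ...)."""


@dataclass
class BoundaryLoop:
    """Ordered vertex indices along one boundary component.

    Consecutive entries (cyclically) share a boundary edge; the ordering
    follows the winding of the triangles owning those edges.
    """

    vertices: np.ndarray

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class TriSurfaceMesh:
    """An oriented triangle surface with optional per-vertex region labels."""

    vertices: np.ndarray
    triangles: np.ndarray
    region_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.region_labels is None:
            self.region_labels = np.full(len(self.vertices), "unlabeled", dtype=object)
        else:
            self.region_labels = np.asarray(self.region_labels, dtype=object)
            if len(self.region_labels) != len(self.vertices):
                raise MeshError(
                    f"{len(self.region_labels)} labels for {len(self.vertices)} vertices"
                )

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "TriSurfaceMesh":
        return TriSurfaceMesh(
            self.vertices.copy(), self.triangles.copy(), self.region_labels.copy()
        )

    def mesh_id(self) -> str:
        """Content hash binding frame sets and transfer matrices to a mesh."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(np.round(self.vertices, 9)).tobytes())
        h.update(np.ascontiguousarray(self.triangles).tobytes())
        return h.hexdigest()[:16]

    # ------------------------------------------------------------- connectivity
    def directed_edges(self) -> np.ndarray:
        """(3F, 2) array of directed edges following triangle winding."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]], axis=0)

    def undirected_edges(self) -> np.ndarray:
        """Unique undirected edges, each as a sorted (lo, hi) pair."""
        de = np.sort(self.directed_edges(), axis=1)
        return np.unique(de, axis=0)

    def boundary_directed_edges(self) -> np.ndarray:
        """Directed edges whose reverse does not occur (i.e. boundary edges)."""
        de = self.directed_edges()
        fwd = {(int(a), int(b)) for a, b in de}
        mask = [((b, a) not in fwd) for a, b in de]
        return de[np.asarray(mask, dtype=bool)]

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.undirected_edges()) + self.n_triangles

    def is_closed(self) -> bool:
        return len(self.boundary_directed_edges()) == 0

    # --------------------------------------------------------------- geometry
    def triangle_normals(self, normalized: bool = True) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, k]] for k in range(3))
        n = np.cross(b - a, c - a)
        if normalized:
            n = n / np.linalg.norm(n, axis=1, keepdims=True)
        return n

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(normalized=False), axis=1)

    # ------------------------------------------------------------- validation
    def validate(self, require_closed: bool = False) -> None:
        """Raise MeshError unless all structural invariants hold."""
        if self.n_vertices == 0 or self.n_triangles == 0:
            raise MeshError("empty mesh")
        t = self.triangles
        if t.min() < 0 or t.max() >= self.n_vertices:
            raise MeshError(
                f"triangle index out of range: {t.min()}..{t.max()} "
                f"for {self.n_vertices} vertices"
            )
        degenerate = (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        if degenerate.any():
            raise MeshError(f"triangle {int(np.where(degenerate)[0][0])} repeats a vertex")
        areas = self.triangle_areas()
        if (areas <= _MIN_TRIANGLE_AREA).any():
            raise MeshError(
                f"zero-area triangle {int(np.argmin(areas))} (area={areas.min():.3g})"
            )
        # orientation: no directed edge may repeat, no undirected edge used >2x
        de = self.directed_edges()
        uniq, counts = np.unique(de, axis=0, return_counts=True)
        if (counts > 1).any():
            a, b = uniq[counts > 1][0]
            raise MeshTopologyError(
                f"inconsistent orientation: directed edge ({a},{b}) repeated"
            )
        ue = np.sort(de, axis=1)
        uniq_u, counts_u = np.unique(ue, axis=0, return_counts=True)
        if (counts_u > 2).any():
            a, b = uniq_u[counts_u > 2][0]
            raise MeshTopologyError(f"non-manifold edge ({a},{b}) used by >2 triangles")
        if require_closed:
            if (counts_u != 2).any():
                raise MeshTopologyError("mesh flagged closed but has boundary edges")
            if self.euler_characteristic() != 2:
                raise MeshTopologyError(
                    f"closed mesh has Euler characteristic "
                    f"{self.euler_characteristic()} != 2"
                )


# =========================================================================== I/O

_FORMATS = ("ptsfac", "off", "ply")


def _label_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels")


def _write_labels(mesh: TriSurfaceMesh, path: Path) -> None:
    if all(l == "unlabeled" for l in mesh.region_labels):
        return
    _label_sidecar(path).write_text("\n".join(str(l) for l in mesh.region_labels) + "\n")


def _read_labels(path: Path, n_vertices: int) -> np.ndarray | None:
    side = _label_sidecar(path)
    if not side.exists():
        return None
    labels = side.read_text().split()
    if len(labels) != n_vertices:
        raise MeshFormatError(
            f"{side}: {len(labels)} labels for {n_vertices} vertices"
        )
    return np.array(labels, dtype=object)


def _parse_floats(line: str, n: int, path: Path, lineno: int) -> list[float]:
    parts = line.split()
    if len(parts) < n:
        raise MeshFormatError(f"{path}:{lineno}: expected {n} numbers, got {len(parts)}")
    try:
        return [float(p) for p in parts[:n]]
    except ValueError as exc:
        raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc


def _parse_ints(line: str, n: int, path: Path, lineno: int) -> list[int]:
    parts = line.split()
    if len(parts) < n:
        raise MeshFormatError(f"{path}:{lineno}: expected {n} integers, got {len(parts)}")
    try:
        return [int(float(p)) for p in parts[:n]]
    except ValueError as exc:
        raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc


def _ptsfac_base(path: Path) -> Path:
    if path.suffix in (".pts", ".fac"):
        return path.with_suffix("")
    return path


def load_mesh(path: str | Path, format: str | None = None) -> TriSurfaceMesh:
    """Load and validate a surface mesh.

    ``format`` is one of ``ptsfac``, ``off``, ``ply``; when omitted it is
    inferred from the file suffix.  ``.pts``/``.fac`` triangle indices are
    1-based on disk and converted to 0-based here.
    """
    path = Path(path)
    if format is None:
        format = {".pts": "ptsfac", ".fac": "ptsfac", ".off": "off", ".ply": "ply"}.get(
            path.suffix
        )
        if format is None:
            raise MeshFormatError(f"cannot infer format from suffix of {path}")
    if format not in _FORMATS:
        raise MeshFormatError(f"unknown format {format!r}")

    if format == "ptsfac":
        base = _ptsfac_base(path)
        pts_path, fac_path = base.with_suffix(".pts"), base.with_suffix(".fac")
        verts, tris = [], []
        with open(pts_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    verts.append(_parse_floats(line, 3, pts_path, lineno))
        with open(fac_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.strip():
                    ijk = _parse_ints(line, 3, fac_path, lineno)
                    if min(ijk) < 1 or max(ijk) > len(verts):
                        raise MeshFormatError(
                            f"{fac_path}:{lineno}: index out of range "
                            f"(1-based, {len(verts)} vertices)"
                        )
                    tris.append([k - 1 for k in ijk])
        mesh = TriSurfaceMesh(np.array(verts), np.array(tris))
        labels = _read_labels(pts_path, len(verts))
    elif format == "off":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].strip() != "OFF":
            raise MeshFormatError(f"{path}:1: missing OFF header")
        body = [
            (i + 1, l) for i, l in enumerate(lines[1:], 1)
            if l.strip() and not l.lstrip().startswith("#")
        ]
        lineno0, counts_line = body[0]
        nv, nf, _ = _parse_ints(counts_line, 3, path, lineno0)
        if len(body) - 1 < nv + nf:
            raise MeshFormatError(f"{path}: expected {nv} vertices + {nf} faces")
        verts = [_parse_floats(l, 3, path, ln) for ln, l in body[1 : 1 + nv]]
        tris = []
        for ln, l in body[1 + nv : 1 + nv + nf]:
            vals = _parse_ints(l, 4, path, ln)
            if vals[0] != 3:
                raise MeshFormatError(f"{path}:{ln}: only triangles supported")
            if min(vals[1:4]) < 0 or max(vals[1:4]) >= nv:
                raise MeshFormatError(f"{path}:{ln}: index out of range")
            tris.append(vals[1:4])
        mesh = TriSurfaceMesh(np.array(verts), np.array(tris))
        labels = _read_labels(path, nv)
    else:  # ply (ascii)
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].strip() != "ply":
            raise MeshFormatError(f"{path}:1: missing ply magic")
        nv = nf = None
        header_end = None
        for i, line in enumerate(lines[1:], 1):
            tok = line.split()
            if tok[:2] == ["format", "binary_little_endian"] or tok[:2] == [
                "format",
                "binary_big_endian",
            ]:
                raise MeshFormatError(f"{path}:{i+1}: binary PLY not supported")
            if tok[:2] == ["element", "vertex"]:
                nv = int(tok[2])
            elif tok[:2] == ["element", "face"]:
                nf = int(tok[2])
            elif tok[:1] == ["end_header"]:
                header_end = i
                break
        if nv is None or nf is None or header_end is None:
            raise MeshFormatError(f"{path}: incomplete PLY header")
        data = [
            (ln, l) for ln, l in enumerate(lines[header_end + 1 :], header_end + 2)
            if l.strip()
        ]
        if len(data) < nv + nf:
            raise MeshFormatError(f"{path}: expected {nv} vertices + {nf} faces")
        verts = [_parse_floats(l, 3, path, ln) for ln, l in data[:nv]]
        tris = []
        for ln, l in data[nv : nv + nf]:
            vals = _parse_ints(l, 4, path, ln)
            if vals[0] != 3:
                raise MeshFormatError(f"{path}:{ln}: only triangles supported")
            if min(vals[1:4]) < 0 or max(vals[1:4]) >= nv:
                raise MeshFormatError(f"{path}:{ln}: index out of range")
            tris.append(vals[1:4])
        mesh = TriSurfaceMesh(np.array(verts), np.array(tris))
        labels = _read_labels(path, nv)

    if labels is not None:
        mesh.region_labels = labels
    mesh.validate()
    return mesh


def save_mesh(mesh: TriSurfaceMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh; coordinates keep 9 significant digits.

    Region labels (when any vertex is labeled) go to a ``<file>.labels``
    sidecar with one token per vertex.
    """
    mesh.validate()
    path = Path(path)
    if format is None:
        format = {".pts": "ptsfac", ".fac": "ptsfac", ".off": "off", ".ply": "ply"}.get(
            path.suffix
        )
        if format is None:
            raise MeshFormatError(f"cannot infer format from suffix of {path}")
    if format not in _FORMATS:
        raise MeshFormatError(f"unknown format {format!r}")

    def fmt(v: float) -> str:
        return f"{v:.9g}"

    if format == "ptsfac":
        base = _ptsfac_base(path)
        with open(base.with_suffix(".pts"), "w") as fh:
            for v in mesh.vertices:
                fh.write(f"{fmt(v[0])} {fmt(v[1])} {fmt(v[2])}\n")
        with open(base.with_suffix(".fac"), "w") as fh:
            for t in mesh.triangles:
                fh.write(f"{t[0]+1} {t[1]+1} {t[2]+1}\n")
        _write_labels(mesh, base.with_suffix(".pts"))
    elif format == "off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
            for v in mesh.vertices:
                fh.write(f"{fmt(v[0])} {fmt(v[1])} {fmt(v[2])}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        _write_labels(mesh, path)
    else:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {mesh.n_triangles}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{fmt(v[0])} {fmt(v[1])} {fmt(v[2])}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        _write_labels(mesh, path)


# ================================================================ boundary loops


def boundary_loops(mesh: TriSurfaceMesh) -> list[BoundaryLoop]:
    """One BoundaryLoop per boundary component; closed mesh gives [].

    Raises MeshTopologyError for non-manifold edges or branching boundaries.
    """
    mesh.validate()
    bde = mesh.boundary_directed_edges()
    if len(bde) == 0:
        return []
    succ: dict[int, int] = {}
    for a, b in bde:
        a, b = int(a), int(b)
        if a in succ:
            raise MeshTopologyError(f"boundary branches at vertex {a}")
        succ[a] = b
    loops = []
    remaining = dict(succ)
    while remaining:
        start = min(remaining)  # deterministic loop order / start
        loop = [start]
        cur = remaining.pop(start)
        while cur != start:
            loop.append(cur)
            if cur not in remaining:
                raise MeshTopologyError(f"boundary walk stuck at vertex {cur}")
            cur = remaining.pop(cur)
        loops.append(BoundaryLoop(np.array(loop, dtype=np.int64)))
    return loops


# ================================================================ ellipsoid fit


def fit_ellipsoid(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares ellipsoid through scattered points.

    Algebraic fit of the general quadric with trace normalization
    A+B+C = 1.  When the design is rank-deficient (e.g. near-coplanar rings)
    or the quadric is not an ellipsoid, falls back to the linear (Kasa)
    sphere fit, which is a valid ellipsoid and exact for spherical data.

    Returns (center, rotation, radii): columns of ``rotation`` are principal
    axes, ``radii`` the semi-axes along them.
    """
    pts = np.asarray(points, dtype=float)
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]

    def sphere_fit() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        M = np.column_stack([2 * x, 2 * y, 2 * z, np.ones_like(x)])
        rhs = x**2 + y**2 + z**2
        sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        center = sol[:3]
        r2 = sol[3] + center @ center
        if r2 <= 0:
            raise MeshError("degenerate sphere fit")
        return center, np.eye(3), np.full(3, np.sqrt(r2))

    # general quadric with C = 1 - A - B substituted
    M = np.column_stack(
        [x**2 - z**2, y**2 - z**2, x * y, x * z, y * z, x, y, z, np.ones_like(x)]
    )
    rhs = -(z**2)
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[0] <= 0 or sv[-1] / sv[0] < 1e-9:
        return sphere_fit()
    sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    A, B = sol[0], sol[1]
    C = 1.0 - A - B
    D, E, F, G, H, I = sol[2:8]
    J = sol[8]
    Q = np.array([[A, D / 2, E / 2], [D / 2, B, F / 2], [E / 2, F / 2, C]])
    lam, vec = np.linalg.eigh(Q)
    if lam.min() <= 1e-9 * max(abs(lam).max(), 1e-30):
        return sphere_fit()
    g = np.array([G, H, I])
    center = np.linalg.solve(Q, -g / 2)
    k = center @ Q @ center - J
    if k <= 0:
        return sphere_fit()
    radii = np.sqrt(k / lam)
    return center, vec, radii


def cap_open_mesh(mesh: TriSurfaceMesh, cap_resolution: int = 3) -> TriSurfaceMesh:
    """Close a single-boundary open mesh with an ellipsoidal cap.

    An ellipsoid is fit to the boundary-loop vertices; cap vertices are
    placed on it in ``cap_resolution`` concentric rings (plus a pole) and
    stitched to the loop.  Added vertices get label ``cap``.
    """
    if cap_resolution < 1:
        raise ValueError("cap_resolution must be >= 1")
    loops = boundary_loops(mesh)
    if len(loops) != 1:
        raise MeshError(f"cap_open_mesh needs exactly 1 boundary loop, found {len(loops)}")
    loop = loops[0].vertices
    n_loop = len(loop)
    loop_pts = mesh.vertices[loop]

    center, rot, radii = fit_ellipsoid(loop_pts)

    # unit-sphere directions of the loop in the ellipsoid's principal frame
    w = (loop_pts - center) @ rot / radii
    w = w / np.linalg.norm(w, axis=1, keepdims=True)

    # pole direction: away from the mesh body, through the hole
    d0 = loop_pts.mean(axis=0) - mesh.vertices.mean(axis=0)
    p = (rot.T @ d0) / radii  # map direction into sphere frame consistently
    nrm = np.linalg.norm(p)
    if nrm < 1e-12:
        p = w.mean(axis=0)
        nrm = np.linalg.norm(p)
    p = p / nrm

    # per-vertex polar angle from pole and azimuth about it
    seed_axis = np.eye(3)[np.argmin(np.abs(p))]
    e1 = np.cross(p, seed_axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(p, e1)
    theta = np.arccos(np.clip(w @ p, -1, 1))
    phi = np.arctan2(w @ e2, w @ e1)

    def on_ellipsoid(th: np.ndarray, ph: np.ndarray) -> np.ndarray:
        u = (
            np.sin(th)[:, None] * (np.cos(ph)[:, None] * e1 + np.sin(ph)[:, None] * e2)
            + np.cos(th)[:, None] * p
        )
        return center + (u * radii) @ rot.T

    new_verts = [on_ellipsoid(np.zeros(1), np.zeros(1))[0]]  # pole
    rows: list[np.ndarray] = []  # vertex indices per ring, aligned with loop order
    nv0 = mesh.n_vertices
    for k in range(1, cap_resolution):
        th = theta * (k / cap_resolution)
        ring_pts = on_ellipsoid(th, phi)
        rows.append(np.arange(nv0 + len(new_verts), nv0 + len(new_verts) + n_loop))
        new_verts.extend(ring_pts)
    rows.append(loop)  # outermost "ring" is the loop itself

    tris = []
    pole = nv0
    first = rows[0]
    for i in range(n_loop):
        tris.append([pole, first[i], first[(i + 1) % n_loop]])
    verts_all = np.vstack([mesh.vertices, np.array(new_verts)])
    for ra, rb in zip(rows[:-1], rows[1:]):
        for i in range(n_loop):
            j = (i + 1) % n_loop
            a0, a1 = ra[i], ra[j]
            b0, b1 = rb[i], rb[j]
            # split each quad along its shorter diagonal (tie: lower index pair)
            d_a0b1 = np.linalg.norm(verts_all[a0] - verts_all[b1])
            d_a1b0 = np.linalg.norm(verts_all[a1] - verts_all[b0])
            if d_a0b1 < d_a1b0 or (d_a0b1 == d_a1b0 and (a0, b1) <= (a1, b0)):
                tris.append([a0, b0, b1])
                tris.append([a0, b1, a1])
            else:
                tris.append([a0, b0, a1])
                tris.append([a1, b0, b1])
    cap_tris = np.array(tris, dtype=np.int64)

    labels = np.concatenate(
        [mesh.region_labels, np.full(len(new_verts), "cap", dtype=object)]
    )

    def build(cap: np.ndarray) -> TriSurfaceMesh:
        return TriSurfaceMesh(verts_all, np.vstack([mesh.triangles, cap]), labels)

    closed = build(cap_tris)
    try:
        closed.validate(require_closed=True)
    except MeshTopologyError:
        closed = build(cap_tris[:, ::-1])  # uniform flip if winding sense was wrong
        closed.validate(require_closed=True)
    return closed
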