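"""Synthetic heart-in-torso scenes, dipole source time courses, and the
concentric-shell harmonic solution used as the forward-solver oracle.

The scenes emulate the structure of the experimental datasets this kind of
study uses: a closed source surface of a few hundred nodes, split into
ventricular and atrial regions by an AV plane, inside a torso-shaped outer
surface.  Potentials come from a small set of moving current dipoles in an
infinite homogeneous medium -- smooth, deterministic, and reproducible from
the declared trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import sph_harm_y

from .frames import PotentialFrameSet
from .geometry import points_inside_mesh
from .mesh import TriSurfaceMesh

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: default homogeneous torso conductivity, S/m (cancels in all error ratios)
DEFAULT_CONDUCTIVITY = 0.2


# ------------------------------------------------------------------ primitives


def make_icosphere(radius: float, subdivisions: int) -> TriSurfaceMesh:
    """Geodesic sphere: subdivided icosahedron projected to ``radius``.

    F = 20 * 4**subdivisions, V = 10 * 4**subdivisions + 2.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    mesh = TriSurfaceMesh(verts * radius, faces)
    mesh.validate(require_closed=True)
    return mesh


def _hull_mesh(points: np.ndarray) -> TriSurfaceMesh:
    """Closed outward-oriented surface = convex hull of the given points."""
    hull = ConvexHull(points)
    used = np.unique(hull.simplices)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = points[used]
    tris = remap[hull.simplices]
    center = verts.mean(axis=0)
    a, b, c = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    normals = np.cross(b - a, c - a)
    inward = np.einsum("ij,ij->i", normals, (a + b + c) / 3.0 - center) < 0
    tris[inward] = tris[inward][:, ::-1]
    mesh = TriSurfaceMesh(verts, tris)
    mesh.validate(require_closed=True)
    return mesh


def fibonacci_sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere directions (golden-angle lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = GOLDEN_ANGLE * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _ellipsoid_mesh(semi_axes: np.ndarray, n_nodes: int) -> TriSurfaceMesh:
    pts = fibonacci_sphere_points(n_nodes) * np.asarray(semi_axes, dtype=float)
    return _hull_mesh(pts)


def _capsule_mesh(radius: float, cyl_height: float, n_nodes: int) -> TriSurfaceMesh:
    """Cylinder with hemispherical caps (convex), area-uniform sampling."""
    side_area = 2 * np.pi * radius * cyl_height
    cap_area = 4 * np.pi * radius**2
    frac_side = side_area / (side_area + cap_area)
    n_side = max(4, int(round(n_nodes * frac_side)))
    n_caps = n_nodes - n_side
    i = np.arange(n_side)
    z = (i + 0.5) / n_side * cyl_height - cyl_height / 2.0
    phi = GOLDEN_ANGLE * i
    side = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])
    caps = fibonacci_sphere_points(n_caps) * radius
    caps[:, 2] += np.sign(caps[:, 2]) * cyl_height / 2.0
    return _hull_mesh(np.vstack([side, caps]))


# ----------------------------------------------------------------------- scene


@dataclass
class Scene:
    """Closed source surface inside a closed torso surface.

    Heart vertices are partitioned into ventricular and atrial labels by the
    plane ``long_axis . x = av_plane_z``; conductivity is homogeneous.
    """

    heart: TriSurfaceMesh
    torso: TriSurfaceMesh
    conductivity: float = DEFAULT_CONDUCTIVITY
    av_plane_z: float = 0.0
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def long_axis_coord(self, points: np.ndarray | None = None) -> np.ndarray:
        if points is None:
            points = self.heart.vertices
        return np.asarray(points) @ self.long_axis

    @property
    def atrial_idx(self) -> np.ndarray:
        return np.flatnonzero(self.heart.region_labels == "atrial")

    @property
    def ventricular_idx(self) -> np.ndarray:
        return np.flatnonzero(self.heart.region_labels == "ventricular")

    def validate(self) -> None:
        self.heart.validate(require_closed=True)
        self.torso.validate(require_closed=True)
        labeled = set(np.unique(self.heart.region_labels))
        if not labeled <= {"ventricular", "atrial", "cap"}:
            raise ValueError(f"unexpected heart labels {labeled}")
        if not points_inside_mesh(self.heart.vertices, self.torso).all():
            raise ValueError("heart vertices not strictly inside torso")


_PRESETS = ("sock_like", "cage_like")

# dataset-scale dimensions, mm: heart ~6x6x7 cm, cage ~10x10x15 cm,
# torso ~36x22x40 cm
_SOCK_HEART_SEMI = np.array([30.0, 30.0, 35.0])
_TORSO_SEMI = np.array([180.0, 110.0, 200.0])
_CAGE_RADIUS, _CAGE_CYL_HEIGHT = 50.0, 50.0  # total height 150 mm with caps


def make_scene(
    preset: str,
    heart_nodes_target: int = 500,
    torso_nodes_target: int = 770,
    atrial_fraction: float = 0.25,
) -> Scene:
    """Deterministic synthetic scene at roughly the requested node counts."""
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")
    if heart_nodes_target < 50 or torso_nodes_target < 50:
        raise ValueError("node targets must be >= 50")
    if preset == "sock_like":
        heart = _ellipsoid_mesh(_SOCK_HEART_SEMI, heart_nodes_target)
    else:
        heart = _capsule_mesh(_CAGE_RADIUS, _CAGE_CYL_HEIGHT, heart_nodes_target)
    torso = _ellipsoid_mesh(_TORSO_SEMI, torso_nodes_target)
    heart_extent = np.abs(heart.vertices).max(axis=0)
    if (heart_extent >= _TORSO_SEMI).any():
        raise ValueError("torso smaller than heart")
    long_axis = np.array([0.0, 0.0, 1.0])
    zc = heart.vertices @ long_axis
    av_plane_z = float(np.quantile(zc, 1.0 - atrial_fraction))
    labels = np.where(zc > av_plane_z, "atrial", "ventricular").astype(object)
    heart.region_labels = labels
    torso.region_labels = np.full(torso.n_vertices, "torso", dtype=object)
    scene = Scene(heart=heart, torso=torso, av_plane_z=av_plane_z, long_axis=long_axis)
    scene.validate()
    return scene


# --------------------------------------------------------------------- dipoles


@dataclass
class DipoleSource:
    """Current dipole with a per-frame trajectory.

    ``positions``/``moments`` are (n_frames, 3); a static dipole repeats one
    row.  Only moment ratios matter downstream, so units are nominal.
    """

    positions: np.ndarray
    moments: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.moments = np.atleast_2d(np.asarray(self.moments, dtype=float))
        if self.positions.shape != self.moments.shape:
            raise ValueError("positions and moments must have matching shapes")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def at(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        k = 0 if self.n_frames == 1 else frame
        return self.positions[k], self.moments[k]


def dipole_potential(
    source: DipoleSource,
    points: np.ndarray,
    conductivity: float = DEFAULT_CONDUCTIVITY,
    frame: int = 0,
) -> np.ndarray:
    """Infinite-medium potential  phi = p.(r - r0) / (4 pi sigma |r - r0|^3)."""
    pos, mom = source.at(frame)
    r = np.asarray(points, dtype=float).reshape(-1, 3) - pos
    d3 = np.linalg.norm(r, axis=1) ** 3
    if (d3 == 0).any():
        raise ValueError("field point coincides with dipole position")
    return (r @ mom) / (4.0 * np.pi * conductivity * d3)


def generate_frames(
    scene: Scene,
    n_frames: int,
    seed: int,
    n_dipoles: int = 3,
    peak_mv: float = 30.0,
    dipoles: list[DipoleSource] | None = None,
) -> PotentialFrameSet:
    """Dipole-sum potentials on the heart surface over an activation window.

    Default trajectories sweep apex to base along the long axis while the
    moments rotate by 90 degrees, giving spatially non-stationary potentials.
    The frame set's ``sources`` field declares the exact dipoles used, and
    every stored value equals the dipole-potential sum at that vertex.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if dipoles is None:
        rng = np.random.default_rng(seed)
        zc = scene.long_axis_coord()
        z_lo, z_hi = zc.min(), zc.max()
        span = z_hi - z_lo
        # radial scale: stay well inside the surface
        radial = 0.35 * np.linalg.norm(
            scene.heart.vertices - scene.heart.vertices.mean(axis=0), axis=1
        ).mean()
        center = scene.heart.vertices.mean(axis=0)
        axis = scene.long_axis
        seed_ax = np.eye(3)[np.argmin(np.abs(axis))]
        e1 = np.cross(axis, seed_ax)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        s = np.linspace(0.0, 1.0, n_frames)
        dipoles = []
        for k in range(n_dipoles):
            phi0 = rng.uniform(0, 2 * np.pi)
            lag = 0.15 * k / max(1, n_dipoles - 1)
            frac = np.clip(s - lag, 0.0, 1.0)
            z = (z_lo + 0.15 * span) + frac * 0.6 * span - center @ axis
            ang = phi0 + 0.5 * np.pi * s  # slow precession
            pos = (
                center
                + z[:, None] * axis
                + radial * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
            )
            # moment rotates 90 deg from longitudinal toward azimuthal
            rot = 0.5 * np.pi * s
            tang = -np.sin(ang)[:, None] * e1 + np.cos(ang)[:, None] * e2
            mom = np.cos(rot)[:, None] * axis + np.sin(rot)[:, None] * tang
            dipoles.append(DipoleSource(pos, mom))
        inside = points_inside_mesh(
            np.vstack([d.positions for d in dipoles]), scene.heart
        )
        if not inside.all():
            raise RuntimeError("generated dipole trajectory left the heart surface")
        # rescale moments so the peak surface potential is ~peak_mv
        raw = _dipole_sum(dipoles, scene, n_frames)
        scale = peak_mv / np.abs(raw).max()
        dipoles = [DipoleSource(d.positions, d.moments * scale) for d in dipoles]
    values = _dipole_sum(dipoles, scene, n_frames)
    return PotentialFrameSet(
        values, mesh_id=scene.heart.mesh_id(), frame_interval_ms=1.0, sources=dipoles
    )


def _dipole_sum(dipoles: list[DipoleSource], scene: Scene, n_frames: int) -> np.ndarray:
    values = np.zeros((scene.heart.n_vertices, n_frames))
    for t in range(n_frames):
        for d in dipoles:
            values[:, t] += dipole_potential(
                d, scene.heart.vertices, scene.conductivity, frame=t
            )
    return values


# ---------------------------------------------------------------- shell oracle


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real-valued spherical harmonic (polar angle theta, azimuth phi)."""
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


@dataclass
class ShellHarmonicSolution:
    """Laplace solution A r^l Y + B r^-(l+1) Y in a spherical shell.

    Boundary data Y_lm on r = R1 (Dirichlet) and zero radial derivative at
    r = R2 (insulated outer surface).
    """

    l: int
    m: int
    R1: float
    R2: float
    A: float
    B: float

    def _angular(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        r = np.linalg.norm(p, axis=1)
        theta = np.arccos(np.clip(p[:, 2] / r, -1, 1))
        phi = np.arctan2(p[:, 1], p[:, 0])
        return r, theta, phi

    def potential(self, points: np.ndarray) -> np.ndarray:
        r, theta, phi = self._angular(points)
        radial = self.A * r**self.l + self.B * r ** -(self.l + 1)
        return radial * real_sph_harm(self.l, self.m, theta, phi)

    def boundary_values(self, points: np.ndarray) -> np.ndarray:
        """Dirichlet data Y_lm evaluated at the directions of ``points``."""
        _, theta, phi = self._angular(points)
        return real_sph_harm(self.l, self.m, theta, phi)

    def radial_derivative(self, r: float) -> float:
        return self.A * self.l * r ** (self.l - 1) - self.B * (self.l + 1) * r ** -(
            self.l + 2
        )


def shell_solution(l: int, m: int, R1: float, R2: float) -> ShellHarmonicSolution:
    """Solve for (A, B) from the two boundary conditions."""
    if not 0 < R1 < R2:
        raise ValueError("need 0 < R1 < R2")
    M = np.array(
        [
            [R1**l, R1 ** -(l + 1)],
            [l * R2 ** (l - 1), -(l + 1) * R2 ** -(l + 2)],
        ]
    )
    A, B = np.linalg.solve(M, np.array([1.0, 0.0]))
    return ShellHarmonicSolution(l=l, m=m, R1=R1, R2=R2, A=A, B=B)
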