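"""Boundary-element forward solver: epicardial potentials to body-surface
potentials through a homogeneous torso volume.

The region between the closed source surface (Dirichlet data) and the closed
torso surface (insulated, zero normal current) is source-free, so Green's
representation couples the torso potentials and the unknown normal gradient
on the source surface.  Collocation is at vertices; double-layer terms use
exact planar-triangle solid angles and single-layer terms exact 1/R
integrals, both lumped with weight 1/3 per triangle vertex.  Diagonals of the
self solid-angle blocks are set by the row-sum identity so a constant source
potential is reproduced exactly (no separate deflation step is needed: the
constant mode is an exact solution of the discrete system by construction).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .frames import PotentialFrameSet
from .geometry import double_layer_matrix, points_inside_mesh, single_layer_matrix
from .mesh import TriSurfaceMesh
from .scene import Scene

_FOUR_PI = 4.0 * np.pi


class ForwardModelError(Exception):
    pass


@dataclass
class TransferMatrix:
    """Dense linear map: source-surface node potentials -> torso potentials."""

    matrix: np.ndarray  # (n_torso, n_source)
    source_mesh_id: str
    torso_mesh_id: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def apply(self, phi_source: np.ndarray) -> np.ndarray:
        return self.matrix @ phi_source


def transfer_matrix(source: TriSurfaceMesh, torso: TriSurfaceMesh) -> TransferMatrix:
    """Assemble the BEM transfer matrix for a two-surface homogeneous model.

    ``source`` must lie strictly inside ``torso``; both must be closed and
    outward-oriented.
    """
    source.validate(require_closed=True)
    torso.validate(require_closed=True)
    if not points_inside_mesh(source.vertices, torso).all():
        raise ForwardModelError("source surface is not strictly inside the torso")

    xb, xh = torso.vertices, source.vertices
    n_b, n_h = len(xb), len(xh)

    W_bb = double_layer_matrix(xb, torso)
    W_bh = double_layer_matrix(xb, source)
    W_hb = double_layer_matrix(xh, torso)
    W_hh = double_layer_matrix(xh, source)
    S_bh = single_layer_matrix(xb, source)
    S_hh = single_layer_matrix(xh, source)

    # auto-solid-angle diagonals: rows must reproduce a constant potential
    # exactly.  Torso collocation: sum_j W_bb = 4*pi + sum_j W_bh.
    # Source collocation: sum_j W_hh = sum_j W_hb - 4*pi.
    np.fill_diagonal(W_bb, 0.0)
    np.fill_diagonal(
        W_bb, _FOUR_PI + W_bh.sum(axis=1) - W_bb.sum(axis=1)
    )
    np.fill_diagonal(W_hh, 0.0)
    np.fill_diagonal(
        W_hh, W_hb.sum(axis=1) - _FOUR_PI - W_hh.sum(axis=1)
    )

    # unknowns u = [phi_torso; gamma_source]
    M = np.empty((n_b + n_h, n_b + n_h))
    M[:n_b, :n_b] = W_bb - _FOUR_PI * np.eye(n_b)
    M[:n_b, n_b:] = -S_bh
    M[n_b:, :n_b] = W_hb
    M[n_b:, n_b:] = -S_hh
    rhs = np.vstack([W_bh, _FOUR_PI * np.eye(n_h) + W_hh])

    try:
        X = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        cond = np.linalg.cond(M)
        raise ForwardModelError(f"BEM system singular (cond ~ {cond:.3g})") from exc
    T = X[:n_b]
    if not np.isfinite(T).all():
        raise ForwardModelError("non-finite entries in transfer matrix")
    return TransferMatrix(
        matrix=T, source_mesh_id=source.mesh_id(), torso_mesh_id=torso.mesh_id()
    )


def assemble_transfer(scene: Scene) -> TransferMatrix:
    return transfer_matrix(scene.heart, scene.torso)


def forward_solve(T: TransferMatrix, frames: PotentialFrameSet) -> PotentialFrameSet:
    """Apply the transfer matrix frame by frame (quasi-static)."""
    if frames.mesh_id != T.source_mesh_id:
        raise ForwardModelError(
            f"frame set bound to mesh {frames.mesh_id}, transfer matrix expects "
            f"{T.source_mesh_id}"
        )
    return PotentialFrameSet(
        T.matrix @ frames.values,
        mesh_id=T.torso_mesh_id,
        frame_interval_ms=frames.frame_interval_ms,
        units=frames.units,
    )


# ----------------------------------------------------------------- persistence


def save_transfer(T: TransferMatrix, path: str | Path) -> None:
    checksum = hashlib.sha1(np.ascontiguousarray(T.matrix).tobytes()).hexdigest()[:16]
    header = {
        "source_mesh_id": T.source_mesh_id,
        "torso_mesh_id": T.torso_mesh_id,
        "shape": list(T.shape),
        "checksum": checksum,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        for row in T.matrix:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def load_transfer(path: str | Path) -> TransferMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ForwardModelError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if list(matrix.shape) != header["shape"]:
        raise ForwardModelError(f"{path}: shape mismatch against header")
    return TransferMatrix(
        matrix=matrix,
        source_mesh_id=header["source_mesh_id"],
        torso_mesh_id=header["torso_mesh_id"],
    )
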