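"""Per-node, per-time-frame potential matrices bound to a mesh."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class PotentialFrameSet:
    """Node x frame matrix of potentials (mV) on a specific mesh.

    ``mesh_id`` is the content hash of the mesh the rows refer to, so that
    downstream operators can refuse mismatched inputs.  ``sources`` may carry
    the dipole trajectories that generated the values (synthetic data only).
    """

    values: np.ndarray  # (n_nodes, n_frames), mV
    mesh_id: str
    frame_interval_ms: float = 1.0
    units: str = "mV"
    sources: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_nodes, n_frames)")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def frame(self, t: int) -> np.ndarray:
        return self.values[:, t]


def save_frames(frames: PotentialFrameSet, path: str | Path) -> None:
    """Delimited matrix (nodes x frames) preceded by a one-line JSON header."""
    header = {
        "mesh_id": frames.mesh_id,
        "units": frames.units,
        "frame_interval_ms": frames.frame_interval_ms,
        "n_nodes": frames.n_nodes,
        "n_frames": frames.n_frames,
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        for row in frames.values:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def load_frames(path: str | Path) -> PotentialFrameSet:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if values.shape != (header["n_nodes"], header["n_frames"]):
        raise ValueError(
            f"{path}: matrix shape {values.shape} does not match header "
            f"({header['n_nodes']}, {header['n_frames']})"
        )
    return PotentialFrameSet(
        values,
        mesh_id=header["mesh_id"],
        frame_interval_ms=header["frame_interval_ms"],
        units=header.get("units", "mV"),
    )
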