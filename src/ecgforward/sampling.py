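"""Incremental source-sampling plans over the heart surface.

Five additive strategies start from a ventricle-only electrode set and add
atrial nodes over ``n_iterations`` bands until the whole surface is measured:

* ``av_first``   -- bands ordered by increasing long-axis distance from the
                    AV plane (closest to the ventricular sock first)
* ``roof_first`` -- the reverse: atrial roof down to the AV plane
* ``combined``   -- each band takes half its quota from each end
* ``uniform``    -- farthest-point sampling order (deterministic spread)
* ``random``     -- seeded uniform random permutation

``plaque_cluster`` picks the k atrial nodes nearest a center (a plaque
electrode array), and ``plan_basal_removal`` removes ventricular nodes in
bands from the base downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scene import Scene

ADDITIVE_STRATEGIES = ("av_first", "roof_first", "combined", "uniform", "random")
ALL_STRATEGIES = ADDITIVE_STRATEGIES + ("plaque", "basal_removal")


class SamplingError(Exception):
    pass


@dataclass
class SamplingPlan:
    """Ordered iterations of cumulative measured-node index sets."""

    mesh_id: str
    strategy: str
    iterations: list[np.ndarray]  # sorted index arrays
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "mesh_id": self.mesh_id,
                "strategy": self.strategy,
                "seed": self.seed,
                "params": self.params,
                "iterations": [it.tolist() for it in self.iterations],
            },
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SamplingPlan":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        d = json.loads(text)
        return cls(
            mesh_id=d["mesh_id"],
            strategy=d["strategy"],
            seed=d["seed"],
            params=d.get("params", {}),
            iterations=[np.array(it, dtype=np.int64) for it in d["iterations"]],
        )


def _split_bands(ordered: np.ndarray, n_iterations: int) -> list[np.ndarray]:
    """Near-equal bands (sizes differ by at most 1), first bands larger."""
    return [b for b in np.array_split(ordered, n_iterations)]


def _atrial_order_av_first(scene: Scene) -> np.ndarray:
    """Atrial nodes by increasing long-axis coordinate; ties by node index."""
    atrial = scene.atrial_idx
    if len(atrial) == 0:
        raise SamplingError("scene has no atrial nodes")
    zc = scene.long_axis_coord()[atrial]
    order = np.lexsort((atrial, zc))
    return atrial[order]


def _cumulative_plan(
    scene: Scene, bands: list[np.ndarray], strategy: str, seed: int | None, **params
) -> SamplingPlan:
    vent = np.sort(scene.ventricular_idx)
    if len(vent) == 0:
        raise SamplingError("scene has no ventricular nodes")
    iterations = [vent]
    cur = vent
    for band in bands:
        cur = np.sort(np.concatenate([cur, band]))
        iterations.append(cur)
    return SamplingPlan(
        mesh_id=scene.heart.mesh_id(),
        strategy=strategy,
        iterations=iterations,
        seed=seed,
        params=params,
    )


def plan_av_first(scene: Scene, n_iterations: int) -> SamplingPlan:
    if n_iterations < 1:
        raise SamplingError("n_iterations must be >= 1")
    ordered = _atrial_order_av_first(scene)
    return _cumulative_plan(
        scene, _split_bands(ordered, n_iterations), "av_first", None,
        n_iterations=n_iterations,
    )


def plan_roof_first(scene: Scene, n_iterations: int) -> SamplingPlan:
    if n_iterations < 1:
        raise SamplingError("n_iterations must be >= 1")
    ordered = _atrial_order_av_first(scene)[::-1]
    return _cumulative_plan(
        scene, _split_bands(ordered, n_iterations), "roof_first", None,
        n_iterations=n_iterations,
    )


def plan_combined(scene: Scene, n_iterations: int) -> SamplingPlan:
    """Each band draws half its quota from the AV end, half from the roof end
    of the AV-first ordering (odd quota: the extra node goes to the AV end)."""
    if n_iterations < 1:
        raise SamplingError("n_iterations must be >= 1")
    ordered = _atrial_order_av_first(scene)
    quotas = [len(b) for b in _split_bands(ordered, n_iterations)]
    bands = []
    lo, hi = 0, len(ordered)
    for q in quotas:
        take_av = (q + 1) // 2
        take_roof = q - take_av
        band = np.concatenate([ordered[lo : lo + take_av], ordered[hi - take_roof : hi]])
        lo += take_av
        hi -= take_roof
        bands.append(band)
    return SamplingPlan(
        mesh_id=scene.heart.mesh_id(),
        strategy="combined",
        iterations=_cumulative_plan(scene, bands, "combined", None).iterations,
        seed=None,
        params={"n_iterations": n_iterations},
    )


def farthest_point_order(points: np.ndarray, start: int) -> np.ndarray:
    """Greedy farthest-point ordering (Euclidean); ties broken by index."""
    n = len(points)
    order = np.empty(n, dtype=np.int64)
    order[0] = start
    dmin = np.linalg.norm(points - points[start], axis=1)
    dmin[start] = -np.inf
    for k in range(1, n):
        nxt = int(np.argmax(dmin))  # argmax takes the lowest index on ties
        order[k] = nxt
        dmin = np.minimum(dmin, np.linalg.norm(points - points[nxt], axis=1))
        dmin[nxt] = -np.inf
    return order


def plan_uniform(scene: Scene, n_iterations: int, seed: int = 0) -> SamplingPlan:
    """Farthest-point sampling over the atrial nodes.

    Seeded at the atrial node nearest the atrial centroid; the ``seed``
    argument is kept for interface symmetry but the ordering is fully
    deterministic given the mesh.
    """
    if n_iterations < 1:
        raise SamplingError("n_iterations must be >= 1")
    atrial = np.sort(scene.atrial_idx)
    if len(atrial) == 0:
        raise SamplingError("scene has no atrial nodes")
    pts = scene.heart.vertices[atrial]
    start = int(np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    ordered = atrial[farthest_point_order(pts, start)]
    return _cumulative_plan(
        scene, _split_bands(ordered, n_iterations), "uniform", seed,
        n_iterations=n_iterations,
    )


def plan_random(scene: Scene, n_iterations: int, seed: int = 0) -> SamplingPlan:
    if n_iterations < 1:
        raise SamplingError("n_iterations must be >= 1")
    atrial = np.sort(scene.atrial_idx)
    if len(atrial) == 0:
        raise SamplingError("scene has no atrial nodes")
    rng = np.random.default_rng(seed)
    ordered = rng.permutation(atrial)
    return _cumulative_plan(
        scene, _split_bands(ordered, n_iterations), "random", seed,
        n_iterations=n_iterations,
    )


_ADDITIVE_PLANNERS = {
    "av_first": plan_av_first,
    "roof_first": plan_roof_first,
    "combined": plan_combined,
    "uniform": plan_uniform,
    "random": plan_random,
}


def make_plan(scene: Scene, strategy: str, n_iterations: int, seed: int = 0) -> SamplingPlan:
    """Dispatch to the named additive strategy (or basal_removal)."""
    if strategy == "basal_removal":
        return plan_basal_removal(scene, n_iterations)
    if strategy not in _ADDITIVE_PLANNERS:
        raise SamplingError(f"unknown strategy {strategy!r}")
    fn = _ADDITIVE_PLANNERS[strategy]
    if strategy in ("uniform", "random"):
        return fn(scene, n_iterations, seed)
    return fn(scene, n_iterations)


def plaque_cluster(scene: Scene, center: np.ndarray, k: int) -> np.ndarray:
    """The k atrial nodes nearest ``center`` (Euclidean, ties by index)."""
    atrial = np.sort(scene.atrial_idx)
    if not 1 <= k <= len(atrial):
        raise SamplingError(f"k={k} out of range 1..{len(atrial)}")
    d = np.linalg.norm(scene.heart.vertices[atrial] - np.asarray(center, dtype=float), axis=1)
    order = np.lexsort((atrial, d))
    return np.sort(atrial[order[:k]])


def plan_basal_removal(
    scene: Scene,
    n_iterations: int,
    include_atria: bool = False,
    removal_fraction: float = 0.5,
) -> SamplingPlan:
    """Remove basal ventricular nodes in bands of decreasing long-axis
    coordinate.

    Iteration 0 is the full ventricular set (plus the atria when
    ``include_atria``); subsequent iterations drop near-equal bands starting
    at the base (highest long-axis coordinate).  At most ``removal_fraction``
    of the ventricular nodes are ever removed, mirroring experiments that
    strip leads from the basal region only and keeping the electrode set
    non-empty.
    """
    if n_iterations < 1:
        raise SamplingError("n_iterations must be >= 1")
    if not 0 < removal_fraction <= 0.9:
        raise SamplingError("removal_fraction must be in (0, 0.9]")
    vent = scene.ventricular_idx
    if len(vent) == 0:
        raise SamplingError("scene has no ventricular nodes")
    zc = scene.long_axis_coord()[vent]
    order = np.lexsort((vent, -zc))  # base (max z) first
    n_removable = max(n_iterations, int(round(removal_fraction * len(vent))))
    ordered = vent[order][:n_removable]
    bands = _split_bands(ordered, n_iterations)
    base = np.sort(scene.atrial_idx) if include_atria else np.array([], dtype=np.int64)
    cur = np.sort(np.concatenate([base, vent]))
    iterations = [cur]
    for band in bands:
        cur = np.setdiff1d(cur, band)
        iterations.append(cur)
    return SamplingPlan(
        mesh_id=scene.heart.mesh_id(),
        strategy="basal_removal",
        iterations=iterations,
        seed=None,
        params={
            "n_iterations": n_iterations,
            "include_atria": include_atria,
            "removal_fraction": removal_fraction,
        },
    )
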