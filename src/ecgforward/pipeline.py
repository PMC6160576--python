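"""End-to-end sampling experiments on a synthetic scene.

Ground truth is the BEM forward solution at *full* source sampling, so the
reported curves isolate sampling-induced error from any solver-family
discrepancy: subsample -> Laplacian-interpolate -> forward-solve -> score
against that ground truth, per strategy and iteration.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bem import TransferMatrix, assemble_transfer, forward_solve
from .frames import PotentialFrameSet
from .interpolation import build_laplacian, make_interpolator
from .metrics import compute_series, summarize
from .sampling import (
    ADDITIVE_STRATEGIES,
    SamplingPlan,
    make_plan,
    plan_basal_removal,
    plaque_cluster,
)
from .scene import Scene, generate_frames, make_scene

REPORT_COLUMNS = [
    "strategy",
    "iteration",
    "n_measured",
    "n_added_atrial",
    "mean_rms",
    "peak_rms",
    "mean_rrmse",
    "peak_rrmse",
    "mean_rho",
    "peak_rho",
    "n_excluded",
    "rms_convention",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    preset: str = "sock_like"
    heart_nodes: int = 500
    torso_nodes: int = 770
    n_frames: int = 20
    n_iterations: int = 7
    strategies: tuple = ADDITIVE_STRATEGIES
    scene_seed: int = 0
    strategy_seed: int = 0
    laplacian_scheme: str = "cotangent"
    rms_convention: str = "sqrt_n"
    window: tuple | None = None
    removal_fraction: float = 0.5
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.strategies:
            raise ValueError("strategies must be non-empty")
        self.strategies = tuple(self.strategies)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strategies"] = list(self.strategies)
        return d


@dataclass
class AblationReport:
    """Per (strategy, iteration) summary table plus run provenance."""

    table: pd.DataFrame
    config: RunConfig
    provenance: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)  # (strategy, iteration) -> ErrorSeries

    def save(self, out_dir: str | Path, stem: str = "ablation") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / f"{stem}.csv", index=False, float_format="%.10g")
        (out / f"{stem}_provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )


def _provenance(config: RunConfig, scene: Scene) -> dict:
    import scipy

    return {
        "config": config.to_dict(),
        "heart_mesh_id": scene.heart.mesh_id(),
        "torso_mesh_id": scene.torso.mesh_id(),
        "versions": {
            "ecgforward": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }


class ExperimentContext:
    """Scene, source frames, transfer matrix and ground truth, built once."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.scene = make_scene(config.preset, config.heart_nodes, config.torso_nodes)
        self.frames = generate_frames(self.scene, config.n_frames, config.scene_seed)
        self.transfer: TransferMatrix = assemble_transfer(self.scene)
        self.ground_truth: PotentialFrameSet = forward_solve(self.transfer, self.frames)
        self.laplacian = build_laplacian(self.scene.heart, config.laplacian_scheme)

    def score_subset(self, measured_idx: np.ndarray):
        """Restrict, interpolate, forward-solve and score one electrode set.

        Returns (summary dict, per-frame ErrorSeries)."""
        interp = make_interpolator(self.laplacian, measured_idx)
        filled = interp(self.frames.values[measured_idx])
        sim = forward_solve(
            self.transfer,
            PotentialFrameSet(
                filled,
                mesh_id=self.frames.mesh_id,
                frame_interval_ms=self.frames.frame_interval_ms,
            ),
        )
        series = compute_series(
            self.ground_truth.values, sim.values, self.config.rms_convention
        )
        return summarize(series, self.config.window), series


def run_ablation(config: RunConfig) -> AblationReport:
    """Score every (strategy, iteration) pair of the configured run."""
    ctx = ExperimentContext(config)
    n_vent = len(ctx.scene.ventricular_idx)
    rows = []
    traces = {}
    for strategy in config.strategies:
        if strategy == "basal_removal":
            plan = plan_basal_removal(
                ctx.scene, config.n_iterations, removal_fraction=config.removal_fraction
            )
        else:
            plan = make_plan(ctx.scene, strategy, config.n_iterations, config.strategy_seed)
        for it, measured in enumerate(plan.iterations):
            try:
                summary, series = ctx.score_subset(measured)
            except Exception as exc:
                raise RuntimeError(
                    f"scoring failed at strategy={strategy} iteration={it}"
                ) from exc
            rows.append(
                {
                    "strategy": strategy,
                    "iteration": it,
                    "n_measured": len(measured),
                    "n_added_atrial": max(0, len(measured) - n_vent),
                    **summary,
                }
            )
            traces[(strategy, it)] = series
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return AblationReport(
        table=table, config=config, provenance=_provenance(config, ctx.scene), traces=traces
    )


def compare_strategies(report: AblationReport, metric: str = "mean_rrmse") -> pd.DataFrame:
    """Rank additive strategies: area under the (n_measured, metric) curve and
    electrodes needed to come within 10% of the full-sampling value.

    Lower is better for both scores.  Strategies must share their electrode
    count grids (guaranteed for the additive strategies of one run).
    """
    tab = report.table
    additive = [s for s in tab["strategy"].unique() if s in ADDITIVE_STRATEGIES]
    if len(additive) < 2:
        raise ValueError("need at least two additive strategies to compare")
    grids = {
        s: tuple(tab.loc[tab["strategy"] == s, "n_measured"]) for s in additive
    }
    if len(set(grids.values())) != 1:
        raise ValueError(f"mismatched electrode grids across strategies: {grids}")
    rows = []
    for s in additive:
        sub = tab[tab["strategy"] == s].sort_values("n_measured")
        x = sub["n_measured"].to_numpy(dtype=float)
        y = sub[metric].to_numpy(dtype=float)
        auc = float(np.trapezoid(y, x))
        full_value = y[-1]
        threshold = 1.1 * full_value
        reach = x[y <= threshold]
        rows.append(
            {
                "strategy": s,
                "auc": auc,
                "electrodes_to_threshold": int(reach[0]) if len(reach) else None,
                "full_value": full_value,
                "metric": metric,
            }
        )
    return pd.DataFrame(rows).sort_values("auc").reset_index(drop=True)


def run_plaque_study(
    config: RunConfig, centers: np.ndarray, k: int
) -> AblationReport:
    """Ventricle + k-node plaque cluster at each center, scored like an
    ablation row; ``k = 0`` reduces to the ventricle-only baseline."""
    ctx = ExperimentContext(config)
    vent = np.sort(ctx.scene.ventricular_idx)
    rows = []
    traces = {}
    baseline, base_series = ctx.score_subset(vent)
    rows.append(
        {
            "strategy": "ventricle_only",
            "iteration": 0,
            "n_measured": len(vent),
            "n_added_atrial": 0,
            **baseline,
        }
    )
    traces[("ventricle_only", 0)] = base_series
    for i, center in enumerate(np.atleast_2d(np.asarray(centers, dtype=float))):
        if k == 0:
            measured = vent
        else:
            cluster = plaque_cluster(ctx.scene, center, k)
            measured = np.sort(np.concatenate([vent, cluster]))
        summary, series = ctx.score_subset(measured)
        rows.append(
            {
                "strategy": "plaque",
                "iteration": i,
                "n_measured": len(measured),
                "n_added_atrial": len(measured) - len(vent),
                **summary,
            }
        )
        traces[("plaque", i)] = series
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return AblationReport(
        table=table, config=config, provenance=_provenance(config, ctx.scene), traces=traces
    )


def default_plaque_centers(scene: Scene, n_centers: int = 6) -> np.ndarray:
    """Spread plaque centers over the atrial surface by farthest-point order,
    starting from the atrial roof (maximal long-axis node)."""
    from .sampling import farthest_point_order

    atrial = np.sort(scene.atrial_idx)
    pts = scene.heart.vertices[atrial]
    zc = scene.long_axis_coord()[atrial]
    start = int(np.argmax(zc))
    order = farthest_point_order(pts, start)
    n_centers = min(n_centers, len(atrial))
    return pts[order[:n_centers]]
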