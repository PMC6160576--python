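# ecgforward

Epicardial-to-torso ECG forward modeling and cardiac source-sampling
experiments on synthetic scenes.

Given a closed cardiac source surface carrying potentials inside a torso
surface, the package computes body-surface potentials with a boundary-element
(BEM) forward solver, fills unsampled source nodes by Laplacian interpolation,
and quantifies the error introduced by incomplete atrial or ventricular
sampling under five incremental electrode-placement strategies, plaque
(electrode-cluster) placement, and incremental basal-lead removal.

## Layout

| module | contents |
| --- | --- |
| `ecgforward.mesh` | triangle-surface data model, validation, `.pts`/`.fac`, OFF and ASCII-PLY I/O, boundary-loop detection, ellipsoidal-cap closure of open (sock-like) meshes |
| `ecgforward.scene` | synthetic heart-in-torso scenes (`sock_like`, `cage_like`), icospheres, moving-dipole source time courses, concentric-shell harmonic oracle |
| `ecgforward.geometry` | exact planar-triangle solid-angle and 1/R integrals shared by the solver |
| `ecgforward.interpolation` | cotangent / inverse-distance surface Laplacians and partial-sampling interpolation |
| `ecgforward.bem` | two-surface transfer-matrix assembly (vertex collocation, analytic singular integrals, row-sum diagonals) and quasi-static forward solves |
| `ecgforward.sampling` | the five additive atrial strategies, plaque clusters, basal removal |
| `ecgforward.metrics` | RMS error, rRMSE, uncentered correlation, window summaries |
| `ecgforward.pipeline` | experiment orchestration, strategy ranking, provenance |

Coordinates are millimetres, potentials millivolts. Ground truth in every
experiment is the same BEM operator applied at full source sampling, so the
reported curves measure sampling-induced error only.

## CLI

```bash
ecgforward synth  --seed 1 --out results/          # scene meshes + source frames
ecgforward ablate --seed 1 --out results/          # incremental-sampling study
ecgforward plaque --seed 1 --out results/          # electrode-cluster study
ecgforward removal --seed 1 --out results/         # basal-removal study
ecgforward report results/ablation.csv --out results/   # strategy ranking
```

All commands accept `--config cfg.yaml` (keys mirror
`ecgforward.pipeline.RunConfig`: preset, node counts, frame count, iteration
count, strategies, seeds, metric convention, summary window). Outputs are a
CSV summary table (one row per strategy/iteration with mean/peak RMS error,
rRMSE and correlation), plus a JSON provenance file echoing the configuration
and library versions. Runs are bit-deterministic given the seeds.

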