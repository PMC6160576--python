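"""Per-frame error metrics between ground-truth and simulated potential maps.

Three metrics are computed per time frame over the torso nodes:

* ``E`` -- root-mean-square difference in mV.  Two denominator conventions
  are offered: ``sqrt_n`` (true RMS, the default) and ``n`` (the literal
  norm-over-n variant some reports print); every summary record names the
  convention used.
* ``rRMSE`` -- ||gt - s|| / ||gt||.
* ``rho`` -- uncentered cosine similarity gt.s / (||gt|| ||s||).  This is
  deliberately *not* Pearson correlation; a mean-centered variant exists
  behind a flag for sensitivity checks only.

Frames whose ground-truth norm is ~0 (below 1e-9 of the window maximum) are
excluded from summaries and counted, since rRMSE and rho are undefined there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RMS_CONVENTIONS = ("sqrt_n", "n")

_ZERO_NORM_REL_TOL = 1e-9


class MetricError(Exception):
    pass


def rms_error(gt: np.ndarray, s: np.ndarray, convention: str = "sqrt_n") -> float:
    gt = np.asarray(gt, dtype=float).ravel()
    s = np.asarray(s, dtype=float).ravel()
    if gt.shape != s.shape:
        raise MetricError(f"length mismatch: {gt.shape} vs {s.shape}")
    if gt.size == 0:
        raise MetricError("empty vectors")
    if convention not in RMS_CONVENTIONS:
        raise MetricError(f"unknown convention {convention!r}")
    nrm = np.linalg.norm(gt - s)
    n = gt.size
    return float(nrm / np.sqrt(n)) if convention == "sqrt_n" else float(nrm / n)


def rrmse(gt: np.ndarray, s: np.ndarray) -> float:
    gt = np.asarray(gt, dtype=float).ravel()
    s = np.asarray(s, dtype=float).ravel()
    if gt.shape != s.shape:
        raise MetricError(f"length mismatch: {gt.shape} vs {s.shape}")
    denom = np.linalg.norm(gt)
    if denom == 0:
        raise MetricError("rRMSE undefined: zero ground-truth norm")
    return float(np.linalg.norm(gt - s) / denom)


def correlation(gt: np.ndarray, s: np.ndarray, centered: bool = False) -> float:
    gt = np.asarray(gt, dtype=float).ravel()
    s = np.asarray(s, dtype=float).ravel()
    if gt.shape != s.shape:
        raise MetricError(f"length mismatch: {gt.shape} vs {s.shape}")
    if centered:
        gt = gt - gt.mean()
        s = s - s.mean()
    ng, ns = np.linalg.norm(gt), np.linalg.norm(s)
    if ng == 0 or ns == 0:
        raise MetricError("correlation undefined: zero-norm input")
    return float(np.clip(gt @ s / (ng * ns), -1.0, 1.0))


@dataclass
class ErrorSeries:
    """Per-frame metric traces; NaN marks frames excluded as undefined."""

    rms: np.ndarray
    rrmse: np.ndarray
    rho: np.ndarray
    n_nodes: int
    rms_convention: str = "sqrt_n"
    excluded_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_frames(self) -> int:
        return len(self.rms)


def compute_series(
    gt: np.ndarray,
    sim: np.ndarray,
    rms_convention: str = "sqrt_n",
) -> ErrorSeries:
    """Metrics per frame for (n_nodes, n_frames) ground-truth/simulated pairs."""
    gt = np.asarray(gt, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if gt.shape != sim.shape or gt.ndim != 2:
        raise MetricError(f"shape mismatch: {gt.shape} vs {sim.shape}")
    n_nodes, n_frames = gt.shape
    norms = np.linalg.norm(gt, axis=0)
    cutoff = _ZERO_NORM_REL_TOL * norms.max() if norms.max() > 0 else 0.0
    excluded = np.flatnonzero(norms <= cutoff)
    rms = np.array([rms_error(gt[:, t], sim[:, t], rms_convention) for t in range(n_frames)])
    rr = np.full(n_frames, np.nan)
    rho = np.full(n_frames, np.nan)
    for t in range(n_frames):
        if t in set(excluded):
            continue
        rr[t] = rrmse(gt[:, t], sim[:, t])
        sn = np.linalg.norm(sim[:, t])
        rho[t] = correlation(gt[:, t], sim[:, t]) if sn > 0 else np.nan
    return ErrorSeries(
        rms=rms,
        rrmse=rr,
        rho=rho,
        n_nodes=n_nodes,
        rms_convention=rms_convention,
        excluded_frames=excluded,
    )


def summarize(series: ErrorSeries, window: tuple[int, int] | None = None) -> dict:
    """Mean and peak summaries over a frame window.

    Peak means worst case: max for RMS error and rRMSE, min for rho.  The
    window is a half-open (start, stop) frame range; None means all frames.
    """
    if window is None:
        lo, hi = 0, series.n_frames
    else:
        lo, hi = window
    if not (0 <= lo < hi <= series.n_frames):
        raise MetricError(f"window {window} outside series of {series.n_frames} frames")
    sl = slice(lo, hi)
    rms, rr, rho = series.rms[sl], series.rrmse[sl], series.rho[sl]
    valid = ~np.isnan(rr)
    if not valid.any():
        raise MetricError("all frames in window are excluded (zero ground truth)")
    return {
        "mean_rms": float(np.mean(rms[valid])),
        "peak_rms": float(np.max(rms[valid])),
        "mean_rrmse": float(np.mean(rr[valid])),
        "peak_rrmse": float(np.max(rr[valid])),
        "mean_rho": float(np.mean(rho[valid])),
        "peak_rho": float(np.min(rho[valid])),
        "n_excluded": int((~valid).sum()),
        "rms_convention": series.rms_convention,
    }
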