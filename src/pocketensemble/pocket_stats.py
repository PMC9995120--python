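"""Equilibrium pocket-volume statistics: P(v), p_open, rolling averages, bootstrap.

Per-frame pocket volumes are reweighted to equilibrium with the MSM frame
weights pi_s / N_s.  The opening probability p_open is the total equilibrium
weight of frames whose pocket volume reaches or exceeds the holo (ligand-
bound) reference volume.  Uncertainty comes from a trajectory-level
bootstrap: whole trajectories are redrawn with replacement, the transition
matrix is re-fit (clustering kept fixed), and the observable recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from pocketensemble.kinetics import (
    DiscreteTrajectories,
    FrameWeights,
    MarkovStateModel,
    fit_msm,
    frame_weights,
)

__all__ = [
    "PocketVolumeSeries",
    "OpeningProbability",
    "BootstrapResult",
    "weighted_volume_distribution",
    "p_open",
    "rolling_average",
    "bootstrap_sem",
    "bootstrap_p_open",
]


@dataclass
class PocketVolumeSeries:
    """Per-frame ligand-site pocket volumes with frame provenance."""

    traj_id: np.ndarray  # str per frame
    frame: np.ndarray  # int per frame
    time_ps: np.ndarray
    volume: np.ndarray  # A^3

    def __post_init__(self) -> None:
        n = len(self.volume)
        self.traj_id = np.asarray(self.traj_id)
        self.frame = np.asarray(self.frame, int)
        self.time_ps = np.asarray(self.time_ps, float)
        self.volume = np.asarray(self.volume, float)
        for name in ("traj_id", "frame", "time_ps"):
            if len(getattr(self, name)) != n:
                raise ValueError("all columns must have equal length")
        if np.any(self.volume < 0):
            raise ValueError("volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.volume)

    @classmethod
    def from_frame_volumes(cls, volumes_per_traj: list[np.ndarray],
                           traj_ids: list[str] | None = None,
                           frame_interval_ps: float = 1.0) -> "PocketVolumeSeries":
        ids, frames, times, vols = [], [], [], []
        for t, v in enumerate(volumes_per_traj):
            v = np.asarray(v, float)
            tid = traj_ids[t] if traj_ids else f"traj{t}"
            ids.append(np.full(v.size, tid))
            frames.append(np.arange(v.size))
            times.append(np.arange(v.size) * frame_interval_ps)
            vols.append(v)
        return cls(np.concatenate(ids), np.concatenate(frames),
                   np.concatenate(times), np.concatenate(vols))

    def per_trajectory(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for tid in pd.unique(self.traj_id):
            mask = self.traj_id == tid
            order = np.argsort(self.frame[mask])
            out[str(tid)] = self.volume[mask][order]
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"traj_id": self.traj_id, "frame": self.frame,
             "time_ps": self.time_ps, "volume_A3": self.volume}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PocketVolumeSeries":
        df = pd.read_csv(path)
        return cls(df["traj_id"].to_numpy(), df["frame"].to_numpy(),
                   df["time_ps"].to_numpy(), df["volume_A3"].to_numpy())


@dataclass
class OpeningProbability:
    """Equilibrium probability that the pocket is at least holo-sized."""

    p_open: float
    holo_volume: float
    sem: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_open <= 1.0 + 1e-12:
            raise ValueError("p_open must be in [0, 1]")


@dataclass
class BootstrapResult:
    n_trials: int
    values: np.ndarray
    mean: float
    sem: float
    seed: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("bootstrap needs at least 2 trials")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


def _aligned_weights(volumes: PocketVolumeSeries, weights: FrameWeights) -> np.ndarray:
    w = weights.concatenated()
    if w.size != len(volumes):
        raise ValueError(
            f"weights cover {w.size} frames, volume series has {len(volumes)}"
        )
    return w


def weighted_volume_distribution(
    volumes: PocketVolumeSeries,
    weights: FrameWeights | np.ndarray,
    bin_width: float = 25.0,
    mode: str = "per_frame",
    state_volumes: np.ndarray | None = None,
    state_probabilities: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MSM-weighted histogram P(v) of pocket volumes; returns (edges, probabilities).

    ``per_frame`` weights every frame's volume by pi_s/N_s (probabilities sum
    to 1 over frames with positive weight).  ``per_state`` reproduces the
    legacy-dataset procedure: one representative volume per state, weighted
    by pi_s (supply ``state_volumes`` and ``state_probabilities``).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mode == "per_frame":
        w = weights if isinstance(weights, np.ndarray) else _aligned_weights(volumes, weights)
        v = volumes.volume
    elif mode == "per_state":
        if state_volumes is None or state_probabilities is None:
            raise ValueError("per_state mode needs state_volumes and state_probabilities")
        v = np.asarray(state_volumes, float)
        w = np.asarray(state_probabilities, float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    active = w > 0
    v, w = v[active], w[active]
    vmax = v.max() if v.size else bin_width
    edges = np.arange(0.0, vmax + 2 * bin_width, bin_width)
    hist, edges = np.histogram(v, bins=edges, weights=w)
    total = w.sum()
    if total <= 0:
        raise ValueError("no frames with positive weight")
    return edges, hist / total


def p_open(
    volumes: PocketVolumeSeries,
    weights: FrameWeights | np.ndarray,
    holo_volume: float,
) -> OpeningProbability:
    """p_open = sum of equilibrium weights of frames with v >= holo_volume (inclusive)."""
    if holo_volume < 0:
        raise ValueError("holo_volume must be non-negative")
    w = weights if isinstance(weights, np.ndarray) else _aligned_weights(volumes, weights)
    total = w.sum()
    if total <= 0:
        raise ValueError("no frames with positive weight")
    p = float(w[volumes.volume >= holo_volume].sum() / total)
    return OpeningProbability(p_open=min(p, 1.0), holo_volume=float(holo_volume))


def rolling_average(values: np.ndarray, window_frames: int) -> np.ndarray:
    """Centered moving mean; edges use the available frames (shrinking window)."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty series")
    w = int(window_frames)
    if w < 1:
        raise ValueError("window must cover at least one frame")
    half_lo = (w - 1) // 2
    half_hi = w // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(v.size)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, v.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def rolling_average_series(series: PocketVolumeSeries, window_ns: float,
                           frame_interval_ps: float) -> PocketVolumeSeries:
    """Apply :func:`rolling_average` per trajectory with a window given in ns."""
    window_frames = max(1, int(round(window_ns * 1000.0 / frame_interval_ps)))
    smoothed = np.empty_like(series.volume)
    for tid in pd.unique(series.traj_id):
        mask = series.traj_id == tid
        order = np.argsort(series.frame[mask])
        sm = rolling_average(series.volume[mask][order], window_frames)
        smoothed[np.flatnonzero(mask)[order]] = sm
    return PocketVolumeSeries(series.traj_id.copy(), series.frame.copy(),
                              series.time_ps.copy(), smoothed)


def bootstrap_sem(
    trajectories: Sequence,
    statistic: Callable[[list], float],
    n_trials: int = 250,
    seed: int = 0,
) -> BootstrapResult:
    """Trajectory-level bootstrap of any statistic over a trajectory set.

    Each trial draws N trajectories with replacement and recomputes
    ``statistic`` on the resample.  Trials raising ``ValueError`` or
    ``RuntimeError`` (e.g. a disconnected resampled MSM) are skipped and
    counted; more than 50% skipped is an error.  The reported SEM is the
    standard deviation of the bootstrap distribution.
    """
    n = len(trajectories)
    if n < 2:
        raise ValueError("need at least 2 trajectories to bootstrap")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    skipped = 0
    for _ in range(n_trials):
        draw = rng.integers(0, n, size=n)
        resample = [trajectories[i] for i in draw]
        try:
            values.append(float(statistic(resample)))
        except (ValueError, RuntimeError):
            skipped += 1
    if skipped > n_trials // 2:
        raise RuntimeError(
            f"{skipped}/{n_trials} bootstrap trials failed; data too sparse"
        )
    if skipped:
        warnings.warn(f"{skipped}/{n_trials} bootstrap trials skipped")
    arr = np.asarray(values)
    return BootstrapResult(
        n_trials=n_trials,
        values=arr,
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1)),
        seed=seed,
        n_skipped=skipped,
    )


def bootstrap_p_open(
    volumes_per_traj: list[np.ndarray],
    dtrajs: DiscreteTrajectories,
    msm_lag: int,
    holo_volume: float,
    n_trials: int = 250,
    seed: int = 0,
    estimator: str = "reversible_mle",
) -> BootstrapResult:
    """Bootstrap SEM of p_open: redraw trajectories, re-fit the transition matrix.

    The state assignment (clustering) is kept fixed; each trial re-estimates
    the MSM on the resampled discrete trajectories and recomputes p_open on
    the resampled volumes.
    """
    if len(volumes_per_traj) != len(dtrajs.dtrajs):
        raise ValueError("volumes and discrete trajectories must align")
    paired = list(zip(volumes_per_traj, dtrajs.dtrajs))

    def stat(resample: list) -> float:
        vols = [v for v, _ in resample]
        dts = DiscreteTrajectories([d for _, d in resample], dtrajs.n_states,
                                   dtrajs.frame_interval_ps)
        msm = fit_msm(dts, msm_lag, estimator=estimator)
        fw = frame_weights(msm, dts)
        series = PocketVolumeSeries.from_frame_volumes(
            vols, frame_interval_ps=dtrajs.frame_interval_ps
        )
        return p_open(series, fw, holo_volume).p_open

    return bootstrap_sem(paired, stat, n_trials=n_trials, seed=seed)
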