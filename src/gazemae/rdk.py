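"""Random-dot kinematogram simulation and net-drift validation.

The simulator realizes the study's probe: a square field of short-lived
dots, a fixed subset of which translates horizontally at the nominal speed
(the signed coherence) while the rest take a fresh uniform-random heading
every frame. It exists to validate that the nominal coherence fed to the
observer model corresponds to the physical net motion of the stimulus; the
behavioral pipeline itself operates on nominal coherence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .schedule import StimulusParams


@dataclass
class DotTrajectory:
    """Frame-by-frame state of the dot field for one probe presentation.

    Arrays ``x``, ``y``, ``age`` and ``heading`` have shape
    (n_frames, n_dots); ``heading[t]`` is the direction a noise dot took
    moving into frame ``t`` (NaN for coherent dots and for frame 0).
    ``coherent`` marks the persistent coherent subset.
    """

    x: np.ndarray
    y: np.ndarray
    age: np.ndarray
    heading: np.ndarray
    coherent: np.ndarray
    coherence_signed: float
    params: StimulusParams

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_coherent(self) -> int:
        return int(self.coherent.sum())


def simulate_rdk(params: StimulusParams, coherence_signed: float,
                 seed: int | np.random.Generator | None = None) -> DotTrajectory:
    """Simulate one probe presentation.

    round(|coherence|/100 x n_dots) dots are assigned to the coherent
    subset once and keep that membership through rebirths, so the per-frame
    coherent count is exact. Coherent dots translate horizontally by
    ``sign(coherence) * speed`` px/frame; the rest move ``speed`` px/frame
    along a heading redrawn uniformly each frame. Dots reaching the
    lifetime are reborn at a uniform position with age 0; initial ages are
    staggered uniformly over [0, lifetime) so rebirths never synchronize.
    Positions wrap toroidally.
    """
    if abs(coherence_signed) > 100:
        raise ParameterError(f"|coherence| must be <= 100, got {coherence_signed}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n, L = params.n_dots, params.field_size
    n_frames = params.n_frames
    n_coh = int(round(abs(coherence_signed) / 100.0 * n))
    sign = 1.0 if coherence_signed > 0 else -1.0

    coherent = np.zeros(n, dtype=bool)
    coherent[rng.permutation(n)[:n_coh]] = True

    x = np.empty((n_frames, n), dtype=float)
    y = np.empty((n_frames, n), dtype=float)
    age = np.empty((n_frames, n), dtype=np.int32)
    heading = np.full((n_frames, n), np.nan)

    x[0] = rng.uniform(0, L, n)
    y[0] = rng.uniform(0, L, n)
    age[0] = rng.integers(0, params.lifetime, n)

    noise = ~coherent
    for t in range(1, n_frames):
        dx = np.where(coherent, sign * params.speed, 0.0)
        dy = np.zeros(n)
        theta = rng.uniform(0, 2 * np.pi, int(noise.sum()))
        dx[noise] = params.speed * np.cos(theta)
        dy[noise] = params.speed * np.sin(theta)
        heading[t, noise] = theta

        x[t] = (x[t - 1] + dx) % L
        y[t] = (y[t - 1] + dy) % L
        age[t] = age[t - 1] + 1

        reborn = age[t] >= params.lifetime
        if reborn.any():
            k = int(reborn.sum())
            x[t, reborn] = rng.uniform(0, L, k)
            y[t, reborn] = rng.uniform(0, L, k)
            age[t, reborn] = 0
            heading[t, reborn] = np.nan

    return DotTrajectory(x=x, y=y, age=age, heading=heading, coherent=coherent,
                         coherence_signed=float(coherence_signed), params=params)


def _signed_displacements(traj: DotTrajectory) -> np.ndarray:
    """Per-dot-frame horizontal displacements, rebirth jumps excluded.

    Wraparound is undone by taking the minimal toroidal image, valid
    because the speed is far below half the field size.
    """
    if traj.n_frames < 2:
        raise DataError("net drift requires a trajectory with at least 2 frames")
    L = traj.params.field_size
    dx = np.diff(traj.x, axis=0)
    dx = (dx + L / 2.0) % L - L / 2.0
    alive = traj.age[1:] > 0  # age 0 at frame t>=1 means the dot was reborn
    return dx[alive]


def estimate_net_drift(traj: DotTrajectory) -> float:
    """Mean signed horizontal displacement per dot per frame (px).

    Averages frame-to-frame displacement over all surviving dot-frames;
    the expectation is coherence/100 x speed.
    """
    return float(_signed_displacements(traj).mean())


def net_drift_stats(traj: DotTrajectory) -> tuple[float, float, int]:
    """Net drift with its standard error and the dot-frame count used."""
    d = _signed_displacements(traj)
    return float(d.mean()), float(d.std(ddof=1) / np.sqrt(d.size)), int(d.size)


def trajectory_frame(traj: DotTrajectory) -> pd.DataFrame:
    """Long-format table (frame, dot, x, y, age, coherent) of a trajectory."""
    f, n = traj.n_frames, traj.params.n_dots
    return pd.DataFrame({
        "frame": np.repeat(np.arange(f), n),
        "dot": np.tile(np.arange(n), f),
        "x": traj.x.ravel(),
        "y": traj.y.ravel(),
        "age": traj.age.ravel(),
        "coherent": np.tile(traj.coherent, f),
    })


def export_trajectory(traj: DotTrajectory, path: str | Path) -> None:
    """Write a trajectory as delimited text."""
    trajectory_frame(traj).to_csv(path, index=False)
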