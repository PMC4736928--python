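"""Trajectory statistics: speeds, turning angles, occupancy, cohesion.

The statistics mirror how recorded fish positions are analysed: the
instantaneous speed at time t is the distance between the positions one
recording interval before and after, divided by two intervals (a centred
three-point estimator); the change of orientation is the signed angle
between successive displacement vectors; immobile ("freezing") samples
with speed not above 1 mm/s are excluded from speed statistics; spatial
use is a normalized occupancy histogram; cohesion is the distribution of
all pairwise inter-agent distances per recorded frame.

Because identity switches make per-individual measures unreliable for
groups, group-level statistics (occupancy, pairwise distances) are the
ones reported for multi-agent data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .arena import Arena, Spot, under_spot
from .engine import TrajectorySet
from .geometry import wrap_angle

__all__ = [
    "SummaryStats",
    "FREEZING_THRESHOLD",
    "instantaneous_speed",
    "turning_angles",
    "filter_freezing",
    "occupancy_grid",
    "pairwise_distances",
    "pooled_turning_angles",
    "regime_conditional_speeds",
    "compute_summary",
]

#: speeds at or below this (m/s) count as freezing and are discarded
FREEZING_THRESHOLD = 1e-3


@dataclass
class SummaryStats:
    """Bundle of trajectory statistics used for reporting and fitting."""

    speeds: dict = field(default_factory=dict)       # regime -> samples (m/s)
    turning: np.ndarray = field(default_factory=lambda: np.empty(0))
    occupancy: Optional[np.ndarray] = None           # normalized 2D grid
    pairwise: Optional[np.ndarray] = None            # pooled distances (m)


def instantaneous_speed(track: np.ndarray, dt_record: float) -> np.ndarray:
    """Three-point speed estimate |P(t+1) - P(t-1)| / (2 dt) per interior
    sample; the two endpoints are omitted.  Fewer than 3 samples give an
    empty result."""
    xy = np.asarray(track, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("track must have shape (T, 2)")
    if dt_record <= 0:
        raise ValueError("dt_record must be > 0")
    if xy.shape[0] < 3:
        return np.empty(0)
    return np.linalg.norm(xy[2:] - xy[:-2], axis=1) / (2.0 * dt_record)


def turning_angles(track: np.ndarray) -> np.ndarray:
    """Signed angle in [-pi, pi) between successive displacement vectors;
    positive turns are to the left.  Samples involving a zero-length
    displacement are skipped."""
    xy = np.asarray(track, dtype=float)
    if xy.shape[0] < 3:
        return np.empty(0)
    disp = np.diff(xy, axis=0)
    lengths = np.linalg.norm(disp, axis=1)
    headings = np.arctan2(disp[:, 1], disp[:, 0])
    ok = (lengths[:-1] > 0) & (lengths[1:] > 0)
    return wrap_angle(headings[1:] - headings[:-1])[ok]


def filter_freezing(speeds: np.ndarray,
                    threshold: float = FREEZING_THRESHOLD) -> np.ndarray:
    """Keep only speeds strictly above the freezing threshold."""
    s = np.asarray(speeds, dtype=float)
    return s[s > threshold]


def occupancy_grid(trajs: TrajectorySet, bin_size: float,
                   arena: Arena) -> np.ndarray:
    """Probability of presence: counts of recorded positions per square
    cell, normalized to sum 1.  ``bin_size`` must divide the arena side."""
    n_bins = arena.side / bin_size
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_size must divide the arena side")
    n_bins = int(round(n_bins))
    pos = trajs.positions.reshape(-1, 2)
    if np.any(pos < 0) or np.any(pos > arena.side):
        raise ValueError("positions outside the arena")
    grid, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=n_bins,
                                range=[[0, arena.side], [0, arena.side]])
    return grid / grid.sum()


def pairwise_distances(trajs: TrajectorySet) -> np.ndarray:
    """All n(n-1)/2 Euclidean inter-agent distances for every recorded
    frame; shape (T, n_pairs)."""
    if trajs.n_agents < 2:
        raise ValueError("pairwise distances require at least 2 agents")
    return np.stack([pdist(trajs.positions[t]) for t in range(trajs.n_frames)])


def pooled_turning_angles(trajs: TrajectorySet,
                          arena: Optional[Arena] = None,
                          min_wall_distance: float = 0.0) -> np.ndarray:
    """Turning angles pooled over all agents.

    With ``min_wall_distance`` > 0 (and an arena), only samples whose full
    three-position window stays at least that far from every wall are
    kept — the protocol used to isolate intrinsic (wall-free) turning when
    calibrating the basic-swimming concentration.
    """
    if min_wall_distance > 0.0 and arena is None:
        raise ValueError("min_wall_distance requires an arena")
    out = []
    for i in range(trajs.n_agents):
        xy = trajs.positions[:, i, :]
        if xy.shape[0] < 3:
            continue
        disp = np.diff(xy, axis=0)
        lengths = np.linalg.norm(disp, axis=1)
        headings = np.arctan2(disp[:, 1], disp[:, 0])
        keep = (lengths[:-1] > 0) & (lengths[1:] > 0)
        if min_wall_distance > 0.0:
            far = np.minimum(xy, arena.side - xy).min(axis=1) >= min_wall_distance
            keep &= far[:-2] & far[1:-1] & far[2:]
        out.append(wrap_angle(np.diff(headings))[keep])
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def regime_conditional_speeds(trajs: TrajectorySet, spots: Sequence[Spot],
                              dt_record: Optional[float] = None) -> dict:
    """Three-point speeds split by spot regime.

    A speed sample at time t is attributed to a regime only when all three
    positions of its window (t-1, t, t+1) fall in the same regime; mixed
    windows are discarded so that spot-boundary crossings do not blend the
    two speed distributions.  With no spots everything is 'homogeneous'.
    """
    if dt_record is None:
        dt_record = trajs.record_interval
    out: dict = {}
    for i in range(trajs.n_agents):
        xy = trajs.positions[:, i, :]
        v = instantaneous_speed(xy, dt_record)
        if not spots:
            out.setdefault("homogeneous", []).append(v)
            continue
        inside = np.array([under_spot(q, spots)[0] for q in xy])
        window_in = inside[:-2] & inside[1:-1] & inside[2:]
        window_out = ~inside[:-2] & ~inside[1:-1] & ~inside[2:]
        out.setdefault("under_spot", []).append(v[window_in])
        out.setdefault("outside_spot", []).append(v[window_out])
    return {k: np.concatenate(v) for k, v in out.items()}


def compute_summary(trajs: TrajectorySet, arena: Arena,
                    spots: Sequence[Spot] = (),
                    occupancy_bin: float = 0.05) -> SummaryStats:
    """All summary statistics of a trajectory set in one pass."""
    speeds = {k: filter_freezing(v)
              for k, v in regime_conditional_speeds(trajs, list(spots)).items()}
    stats = SummaryStats(
        speeds=speeds,
        turning=pooled_turning_angles(trajs),
        occupancy=occupancy_grid(trajs, occupancy_bin, arena),
    )
    if trajs.n_agents >= 2:
        stats.pairwise = pairwise_distances(trajs).ravel()
    return stats
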