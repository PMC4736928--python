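"""Calibration by least squares.

Two fitting protocols are provided:

* :func:`fit_kappa` — the von Mises concentration of a turning-angle
  distribution, found by minimizing the sum of squared differences
  between the binned empirical density and the theoretical von Mises
  density over a grid of candidate kappa values (a rapid, low-cost
  fitting method);
* :func:`grid_search` — a generic brute-force search over named parameter
  grids: for every grid point a forward model produces summary
  statistics, which are compared with a reference by a summed
  squared-difference objective over configurable binned statistics
  (turning distribution, occupancy grid, pairwise-distance distribution).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import SummaryStats, compute_summary
from .decision import von_mises_pdf
from .engine import RunConfig, simulate

__all__ = [
    "FitResult",
    "binned_circular_density",
    "fit_kappa",
    "grid_search",
    "summary_objective",
    "make_simulation_forward",
]

#: default number of bins for turning-angle histograms (5 degree bins)
TURNING_BINS = 72

#: default bin width (m) for pairwise-distance histograms
PAIRWISE_BIN = 0.1


@dataclass
class FitResult:
    """Best parameters, attained objective and the full objective surface
    over the searched grid (one row per grid point)."""

    params: dict
    objective: float
    surface: pd.DataFrame


def binned_circular_density(samples: np.ndarray, n_bins: int = TURNING_BINS
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram density of circular samples on [-pi, pi).

    Returns ``(bin_centres, density)`` with the density normalized so that
    sum(density) * bin_width = 1.
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("binned_circular_density requires samples")
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    density, edges = np.histogram(s, bins=n_bins, range=(-math.pi, math.pi),
                                  density=True)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, density


def fit_kappa(samples: np.ndarray, kappa_grid: Optional[np.ndarray] = None,
              n_bins: int = TURNING_BINS) -> FitResult:
    """Least-squares von Mises concentration fit of turning angles.

    Minimizes sum over bins of (empirical density - von Mises(0, kappa)
    density at the bin centre)^2 over the kappa grid (default 0 to 30 in
    steps of 0.1).
    """
    if kappa_grid is None:
        kappa_grid = np.arange(0.0, 30.0 + 1e-9, 0.1)
    centres, emp = binned_circular_density(samples, n_bins)
    objectives = np.array([
        float(np.sum((emp - von_mises_pdf(centres, 0.0, k)) ** 2))
        for k in kappa_grid
    ])
    best = int(np.argmin(objectives))
    surface = pd.DataFrame({"kappa": kappa_grid, "objective": objectives})
    return FitResult({"kappa": float(kappa_grid[best])},
                     float(objectives[best]), surface)


def _stat_vector(stats: SummaryStats, name: str, max_distance: float) -> np.ndarray:
    """One statistic as a unit-mass vector for the objective."""
    if name == "turning":
        counts, _ = np.histogram(stats.turning, bins=TURNING_BINS,
                                 range=(-math.pi, math.pi))
        total = counts.sum()
        if total == 0:
            raise ValueError("no turning samples")
        return counts / total
    if name == "occupancy":
        if stats.occupancy is None:
            raise ValueError("no occupancy grid")
        return stats.occupancy.ravel()
    if name == "pairwise":
        if stats.pairwise is None:
            raise ValueError("no pairwise distances")
        n_bins = int(math.ceil(max_distance / PAIRWISE_BIN))
        counts, _ = np.histogram(stats.pairwise, bins=n_bins,
                                 range=(0.0, n_bins * PAIRWISE_BIN))
        return counts / counts.sum()
    raise ValueError(f"unknown statistic {name!r}; "
                     "expected 'turning', 'occupancy' or 'pairwise'")


def summary_objective(stats: SummaryStats, reference: SummaryStats,
                      statistics: Sequence[str],
                      max_distance: float = 2.0) -> float:
    """Unweighted sum over statistics of the sum of squared differences of
    unit-mass binned distributions; invariant to statistic ordering."""
    total = 0.0
    for name in sorted(statistics):
        a = _stat_vector(stats, name, max_distance)
        b = _stat_vector(reference, name, max_distance)
        if a.shape != b.shape:
            raise ValueError(f"statistic {name!r} binned differently in "
                             "forward output and reference")
        total += float(np.sum((a - b) ** 2))
    return total


def grid_search(param_grid: Mapping[str, Sequence[float]],
                forward: Callable[[dict], SummaryStats],
                reference: SummaryStats,
                statistics: Sequence[str],
                max_distance: float = 2.0) -> FitResult:
    """Exhaustive search of the forward model over a named parameter grid.

    ``forward`` maps a parameter dict (one value per grid axis) to the
    summary statistics of a (seeded) forward run.  A grid point whose
    forward evaluation raises is recorded with a NaN objective, excluded
    from the argmin and warned about.
    """
    names = list(param_grid)
    if not names or any(len(param_grid[n]) == 0 for n in names):
        raise ValueError("param_grid must be non-empty")
    rows = []
    for combo in itertools.product(*(param_grid[n] for n in names)):
        point = dict(zip(names, combo))
        try:
            stats = forward(dict(point))
            obj = summary_objective(stats, reference, statistics, max_distance)
        except Exception as exc:  # noqa: BLE001 - forward failures are data
            warnings.warn(f"forward model failed at {point}: {exc}",
                          RuntimeWarning, stacklevel=2)
            obj = math.nan
        rows.append({**point, "objective": obj})
    surface = pd.DataFrame(rows)
    finite = surface["objective"].notna()
    if not finite.any():
        raise RuntimeError("forward model failed at every grid point")
    best_row = surface.loc[finite, "objective"].idxmin()
    best = surface.loc[best_row]
    params = {n: float(best[n]) for n in names}
    return FitResult(params, float(best["objective"]), surface)


def make_simulation_forward(base_config: RunConfig,
                            statistics: Sequence[str],
                            n_replicates: int = 3,
                            base_seed: int = 0,
                            occupancy_bin: float = 0.05
                            ) -> Callable[[dict], SummaryStats]:
    """A forward model that simulates ``base_config`` with behavioural
    parameters overridden by the grid point, pooling ``n_replicates``
    seeded replicates into one :class:`SummaryStats`."""

    def forward(point: dict) -> SummaryStats:
        params = replace(base_config.params, **point)
        pooled = SummaryStats()
        turning, pairwise, occ = [], [], []
        for r in range(n_replicates):
            cfg = replace(base_config, params=params,
                          seed=base_seed + 1000 * r)
            trajs = simulate(cfg)
            stats = compute_summary(trajs, cfg.arena, cfg.spots,
                                    occupancy_bin=occupancy_bin)
            turning.append(stats.turning)
            occ.append(stats.occupancy)
            if stats.pairwise is not None:
                pairwise.append(stats.pairwise)
        pooled.turning = np.concatenate(turning)
        pooled.occupancy = np.mean(occ, axis=0)
        if pairwise:
            pooled.pairwise = np.concatenate(pairwise)
        return pooled

    return forward
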