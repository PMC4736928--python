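"""Circular decision model: from percepts to a sampled heading.

Every time step the agent builds a probability density over candidate
headings theta in [-pi, pi) (body frame, 0 = keep going straight):

* with no perceptible stimulus and far from walls, a single von Mises
  centred forwards with concentration kappa0 (basic swimming);
* within the wall-interaction distance d_wall, an equal-weight two-component
  von Mises mixture along the two directions parallel to the nearest wall
  (wall following, concentration kappa_wall);
* each perceived fish / spot adds a von Mises centred on its bearing; the
  components of one stimulus kind are mixed with weights proportional to
  their captured solid angles;
* the global density is the convex combination

      f = (f0 + a* A_Tf fF + b* A_Ts fS) / (1 + a* A_Tf + b* A_Ts)

  where A_Tf, A_Ts are the total solid angles (sr) of fish and spots and
  a*, b* are wall-dependent weights per steradian.

The heading is drawn by inverse transform sampling on the cumulative
trapezoidal integral of the density, evaluated on a uniform angular grid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .geometry import BodyModel, Percept, wrap_angle

__all__ = [
    "BehaviourParams",
    "DirectionPDF",
    "direction_grid",
    "bessel_i0",
    "von_mises_pdf",
    "baseline_pdf",
    "stimulus_mixture_pdf",
    "select_weights",
    "global_pdf",
    "pdf_to_cdf",
    "sample_direction",
]

#: number of grid nodes on [-pi, pi] (0.5 degree spacing, both endpoints
#: included for trapezoidal integration)
GRID_SIZE = 720


@dataclass(frozen=True)
class BehaviourParams:
    """Behavioural parameters of the decision model.

    Defaults are the fitted values for adult zebrafish: dispersions
    kappa0=6.3 (basic swimming), kappa_wall=kappa_fish=kappa_spot=20;
    stimulus weights per steradian alpha0=55 / alpha_wall=20 (fish) and
    beta0=0.15 / beta_wall=0.01 (spots), each fitted in single-stimulus
    conditions; division factors w_fish=2 and w_spot=9 applied when both
    stimulus kinds are present in the scenario; wall-interaction distance
    d_wall=0.05 m; field of view 270 degrees; decision interval dt=1/3 s
    (one tail beat).
    """

    kappa0: float = 6.3
    kappa_wall: float = 20.0
    kappa_fish: float = 20.0
    kappa_spot: float = 20.0
    alpha0: float = 55.0
    alpha_wall: float = 20.0
    beta0: float = 0.15
    beta_wall: float = 0.01
    w_fish: float = 2.0
    w_spot: float = 9.0
    d_wall: float = 0.05
    fov: float = 1.5 * math.pi
    dt: float = 1.0 / 3.0
    body: BodyModel = field(default_factory=BodyModel)
    n_grid: int = GRID_SIZE

    def __post_init__(self):
        for name in ("kappa0", "kappa_wall", "kappa_fish", "kappa_spot",
                     "alpha0", "alpha_wall", "beta0", "beta_wall"):
            if getattr(self, name) < 0:
                raise ValueError(f"BehaviourParams.{name} must be >= 0")
        for name in ("w_fish", "w_spot"):
            if getattr(self, name) < 1:
                raise ValueError(f"BehaviourParams.{name} must be >= 1")
        if self.d_wall <= 0:
            raise ValueError("BehaviourParams.d_wall must be > 0")
        if not 0 < self.fov <= 2 * math.pi:
            raise ValueError("BehaviourParams.fov must be in (0, 2*pi]")
        if self.dt <= 0:
            raise ValueError("BehaviourParams.dt must be > 0")
        if self.n_grid < 16:
            raise ValueError("BehaviourParams.n_grid must be >= 16")


@dataclass
class DirectionPDF:
    """A density over candidate headings on a uniform grid spanning
    [-pi, pi], with its CDF once computed."""

    grid: np.ndarray
    density: np.ndarray
    cdf: Optional[np.ndarray] = None

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def direction_grid(n: int = GRID_SIZE) -> np.ndarray:
    """Uniform angular grid of n nodes spanning [-pi, pi] inclusive."""
    return np.linspace(-math.pi, math.pi, n)


def bessel_i0(kappa: float) -> float:
    """Modified Bessel function of the first kind, order zero,

        I0(kappa) = sum_{k>=0} (kappa/2)^{2k} / (k! Gamma(k+1)),

    summed to relative accuracy 1e-12.
    """
    if kappa < 0:
        raise ValueError("bessel_i0 requires kappa >= 0")
    x = 0.25 * kappa * kappa  # (kappa/2)^2
    term = 1.0
    total = 1.0
    for k in range(1, 1000):
        term *= x / (k * k)
        total += term
        if term < 1e-12 * total:
            break
    return total


def von_mises_pdf(theta, mu: float, kappa: float):
    """von Mises density exp(kappa cos(theta - mu)) / (2 pi I0(kappa));
    the circular analogue of a Gaussian (kappa=0 gives the uniform)."""
    if kappa < 0:
        raise ValueError("von_mises_pdf requires kappa >= 0")
    return np.exp(kappa * np.cos(np.asarray(theta, float) - mu)) / (
        2.0 * math.pi * bessel_i0(kappa)
    )


def baseline_pdf(d: float, wall_dirs, params: BehaviourParams,
                 grid: Optional[np.ndarray] = None) -> DirectionPDF:
    """Stimulus-free heading density.

    Far from walls (d >= d_wall): a single von Mises at mu=0 with kappa0.
    Near a wall (d < d_wall): an equal-weight (1/2, 1/2) mixture of von
    Mises at the two body-frame directions ``wall_dirs`` parallel to the
    nearest wall, with kappa_wall.
    """
    if d < 0:
        raise ValueError("distance to wall must be >= 0")
    if grid is None:
        grid = direction_grid(params.n_grid)
    if d >= params.d_wall:
        density = von_mises_pdf(grid, 0.0, params.kappa0)
    else:
        if wall_dirs is None:
            raise ValueError("wall-following directions required when d < d_wall")
        mu1, mu2 = wall_dirs
        density = 0.5 * (von_mises_pdf(grid, mu1, params.kappa_wall)
                         + von_mises_pdf(grid, mu2, params.kappa_wall))
    return DirectionPDF(grid, density)


def stimulus_mixture_pdf(percepts: Sequence[Percept], kappa: float,
                         grid: Optional[np.ndarray] = None,
                         n_grid: int = GRID_SIZE):
    """Mixture density over one stimulus kind.

    Component i is a von Mises centred on the stimulus bearing; its weight
    is A_i / A_T, the stimulus' share of the total captured solid angle.
    Returns ``(pdf, A_T)`` with A_T the total solid angle in steradians.
    """
    if not percepts:
        raise ValueError("stimulus_mixture_pdf requires at least one percept")
    if grid is None:
        grid = direction_grid(n_grid)
    areas = np.array([p.solid_angle for p in percepts], dtype=float)
    if np.any(areas <= 0):
        raise ValueError("all percept solid angles must be > 0")
    total = float(areas.sum())
    bearings = np.array([p.bearing for p in percepts], dtype=float)
    # (n_components, n_grid) von Mises kernel evaluated in one shot
    kernels = np.exp(kappa * np.cos(grid[None, :] - bearings[:, None]))
    kernels /= 2.0 * math.pi * bessel_i0(kappa)
    density = (areas / total) @ kernels
    return DirectionPDF(grid, density), total


def select_weights(d: float, params: BehaviourParams,
                   fish_present: bool, spots_present: bool) -> tuple[float, float]:
    """Wall-dependent stimulus weights (alpha*, beta*) per steradian.

    alpha* is alpha0 away from walls and alpha_wall within d_wall (same for
    beta*).  When the scenario contains both stimulus kinds, alpha is
    divided by w_fish and beta by w_spot — a configuration-level switch
    reflecting how the mixed condition was calibrated.
    """
    if d < 0:
        raise ValueError("distance to wall must be >= 0")
    alpha = params.alpha0 if d >= params.d_wall else params.alpha_wall
    beta = params.beta0 if d >= params.d_wall else params.beta_wall
    if fish_present and spots_present:
        alpha /= params.w_fish
        beta /= params.w_spot
    return alpha, beta


def global_pdf(f0: DirectionPDF, fF: Optional[DirectionPDF],
               fS: Optional[DirectionPDF], a_tf: float, a_ts: float,
               alpha_star: float, beta_star: float) -> DirectionPDF:
    """Convex combination of baseline, fish and spot densities:

        f = (f0 + alpha* A_Tf fF + beta* A_Ts fS) / (1 + alpha* A_Tf + beta* A_Ts)

    Absent stimulus terms contribute with total solid angle 0.
    """
    wf = alpha_star * a_tf
    ws = beta_star * a_ts
    num = f0.density.copy()
    if fF is not None:
        num += wf * fF.density
    elif wf != 0.0:
        raise ValueError("nonzero fish solid angle with absent fish density")
    if fS is not None:
        num += ws * fS.density
    elif ws != 0.0:
        raise ValueError("nonzero spot solid angle with absent spot density")
    return DirectionPDF(f0.grid, num / (1.0 + wf + ws))


def pdf_to_cdf(pdf: DirectionPDF) -> DirectionPDF:
    """Cumulative trapezoidal integral of the density over [-pi, pi],
    renormalized so that cdf[-1] is exactly 1."""
    if np.any(pdf.density < 0):
        raise ValueError("density must be non-negative")
    cdf = cumulative_trapezoid(pdf.density, pdf.grid, initial=0.0)
    total = cdf[-1]
    if total <= 0.0:
        raise ValueError("degenerate density: zero total mass")
    return DirectionPDF(pdf.grid, pdf.density, cdf / total)


def sample_direction(pdf: DirectionPDF, u):
    """Inverse-transform sample(s) of a heading from the numeric CDF.

    ``u`` is one or many uniform(0, 1) draws.  The inverse CDF is evaluated
    by linear interpolation between grid nodes; in flat CDF regions ties
    resolve to the left node.  Returns angle(s) in [-pi, pi].
    """
    if pdf.cdf is None:
        raise ValueError("call pdf_to_cdf first")
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0.0) | (u_arr > 1.0)):
        raise ValueError("u must lie in [0, 1]")
    cdf, grid = pdf.cdf, pdf.grid
    idx = np.searchsorted(cdf, u_arr, side="left")
    idx = np.clip(idx, 1, len(grid) - 1)
    lo, hi = cdf[idx - 1], cdf[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(hi > lo, (u_arr - lo) / np.maximum(hi - lo, 1e-300), 0.0)
    theta = grid[idx - 1] + frac * (grid[idx] - grid[idx - 1])
    theta = np.where(u_arr <= cdf[0], grid[0], theta)
    if np.ndim(u) == 0:
        return float(theta)
    return theta
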