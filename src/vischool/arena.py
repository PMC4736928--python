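"""Arena geometry, wall interaction, speed regimes and the kinematic update.

The arena is a square tank (default side 1.20 m) with axis-aligned walls,
origin at a corner.  Floating discs ("spots of interest", default radius
0.1 m, 0.05 m above the swimming plane) make the environment heterogeneous:
agents swim slower beneath them.  Positions advance by one decision
interval at a time,

    X(t + dt) = X(t) + v(t + dt) * e(theta(t + dt)) * dt,

with the linear speed drawn independently each step from a per-regime
distribution and the heading sampled by the decision model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import wrap_angle

__all__ = [
    "Arena",
    "Spot",
    "AgentState",
    "SpeedModel",
    "WALL_ORDER",
    "BOUNDARY_MARGIN",
    "distance_to_nearest_wall",
    "wall_following_directions",
    "under_spot",
    "step",
]

#: fixed wall ordering used for deterministic tie-breaks
WALL_ORDER = ("north", "east", "south", "west")

#: clearance (m) left between an agent and a wall when a step is truncated
BOUNDARY_MARGIN = 1e-4


@dataclass(frozen=True)
class Arena:
    """Square tank with side length in metres; coordinates in [0, side]^2."""

    side: float = 1.20

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("Arena.side must be > 0")

    def contains(self, position) -> bool:
        x, y = float(position[0]), float(position[1])
        return 0.0 <= x <= self.side and 0.0 <= y <= self.side

    @property
    def centre(self) -> np.ndarray:
        return np.array([0.5 * self.side, 0.5 * self.side])


@dataclass(frozen=True)
class Spot:
    """Floating disc acting as a shaded, attractive area."""

    centre: tuple[float, float]
    radius: float = 0.1
    height: float = 0.05

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("Spot.radius must be > 0")
        if self.height <= 0:
            raise ValueError("Spot.height must be > 0")

    def validate_inside(self, arena: Arena) -> None:
        cx, cy = self.centre
        if not (self.radius <= cx <= arena.side - self.radius
                and self.radius <= cy <= arena.side - self.radius):
            raise ValueError(f"Spot at {self.centre} not fully inside the arena")


def default_spots(arena: Arena) -> list[Spot]:
    """Two spots on the main diagonal, centres 0.70 m apart, symmetric
    about the arena centre (the experimental layout)."""
    half = 0.35 / math.sqrt(2.0)
    c = 0.5 * arena.side
    return [Spot((c - half, c - half)), Spot((c + half, c + half))]


@dataclass(frozen=True)
class AgentState:
    """Planar position (m), world-frame heading in [-pi, pi) and current
    linear speed (m/s) of one agent."""

    position: np.ndarray
    heading: float
    speed: float

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "heading", float(wrap_angle(self.heading)))
        if self.speed < 0:
            raise ValueError("AgentState.speed must be >= 0")


@dataclass
class SpeedModel:
    """Per-regime instantaneous speed distributions.

    Each regime maps to the (mean, sd) of a normal truncated at zero,
    sampled by rejection; alternatively an empirical pool of speeds can be
    supplied per regime and is drawn from uniformly.  Defaults reproduce
    the measured regimes: 0.07±0.03 m/s in a homogeneous tank, 0.09±0.06
    outside the spots and 0.03±0.02 beneath them.
    """

    regimes: dict = field(default_factory=lambda: {
        "homogeneous": (0.07, 0.03),
        "outside_spot": (0.09, 0.06),
        "under_spot": (0.03, 0.02),
    })
    pools: dict = field(default_factory=dict)

    def sample(self, regime: str, rng: np.random.Generator, size: Optional[int] = None):
        """Independent non-negative draw(s) for the given regime."""
        if regime in self.pools:
            pool = np.asarray(self.pools[regime], dtype=float)
            out = rng.choice(pool, size=size if size is not None else 1)
            return out if size is not None else float(out[0])
        if regime not in self.regimes:
            raise KeyError(
                f"unknown speed regime {regime!r}; known: {sorted(self.regimes)}")
        mean, sd = self.regimes[regime]
        n = size if size is not None else 1
        out = rng.normal(mean, sd, size=n)
        bad = out < 0.0
        while np.any(bad):
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = out < 0.0
        return out if size is not None else float(out[0])


def distance_to_nearest_wall(position, arena: Arena) -> tuple[float, str]:
    """Minimal perpendicular distance to a wall and the wall's identity.

    Ties resolve deterministically by the fixed ordering (N, E, S, W).
    """
    x, y = float(position[0]), float(position[1])
    if not arena.contains(position):
        raise ValueError(f"position {(x, y)} outside the arena")
    dists = np.array([arena.side - y, arena.side - x, y, x])  # N, E, S, W
    idx = int(np.argmin(dists))
    return float(dists[idx]), WALL_ORDER[idx]


def wall_following_directions(wall: str, heading: float) -> tuple[float, float]:
    """The two body-frame directions parallel to the given wall."""
    if wall in ("north", "south"):
        world = (0.0, math.pi)  # walls run east-west
    elif wall in ("east", "west"):
        world = (0.5 * math.pi, -0.5 * math.pi)
    else:
        raise ValueError(f"unknown wall {wall!r}; expected one of {WALL_ORDER}")
    return (float(wrap_angle(world[0] - heading)), float(wrap_angle(world[1] - heading)))


def under_spot(position, spots: Sequence[Spot]) -> tuple[bool, Optional[int]]:
    """Whether the position lies beneath some spot (boundary inclusive)."""
    x, y = float(position[0]), float(position[1])
    for i, spot in enumerate(spots):
        if math.hypot(x - spot.centre[0], y - spot.centre[1]) <= spot.radius:
            return True, i
    return False, None


def step(state: AgentState, theta_rel: float, v: float, dt: float,
         arena: Arena) -> AgentState:
    """Advance one agent by one decision interval.

    The new heading is the old one plus the body-frame turn ``theta_rel``;
    the agent moves v*dt along it.  A step that would cross a wall is
    truncated at the boundary, leaving a clearance of BOUNDARY_MARGIN, with
    the heading unchanged (the wall-following density takes over on the
    next step).
    """
    heading = float(wrap_angle(state.heading + theta_rel))
    disp = v * dt * np.array([math.cos(heading), math.sin(heading)])
    pos = state.position + disp
    if not arena.contains(pos):
        t_exit = 1.0
        for k in range(2):
            if disp[k] > 0 and pos[k] > arena.side:
                t_exit = min(t_exit, (arena.side - state.position[k]) / disp[k])
            elif disp[k] < 0 and pos[k] < 0.0:
                t_exit = min(t_exit, (0.0 - state.position[k]) / disp[k])
        pos = state.position + max(t_exit, 0.0) * disp
    pos = np.clip(pos, BOUNDARY_MARGIN, arena.side - BOUNDARY_MARGIN)
    return AgentState(pos, heading, v)
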