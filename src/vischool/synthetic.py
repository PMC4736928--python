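"""Synthetic reference trajectories.

Generates pseudo-experimental trajectory data with the statistical
structure of tracked zebrafish, so the analysis and fitting pipelines can
be exercised without any video data: a correlated random walk whose
heading increments are von Mises(0, kappa) draws (default kappa = 6.3,
the basic-swimming concentration) and whose per-step speed is drawn from
the regime distribution at the current position (homogeneous 0.07±0.03,
outside spots 0.09±0.06, under spots 0.03±0.02 m/s, normals truncated at
zero).  Positions are truncated at the walls.  A wall-dwell bias — inside
the wall band the heading is steered along the nearest wall, tilted
gently towards the interior the closer the agent gets — emulates the
wall-following of real fish so that trajectories hug the walls instead of
pressing into them; it is a statistical fixture, not a behavioural claim,
and can be disabled for a pure correlated random walk.

The output uses the same trajectory container and table format as the
simulator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .arena import (AgentState, Arena, SpeedModel, Spot,
                    distance_to_nearest_wall, step, under_spot,
                    wall_following_directions)
from .engine import RELEASE_RADIUS, TrajectorySet
from .geometry import wrap_angle

__all__ = ["ReferenceSpec", "generate_reference"]


@dataclass
class ReferenceSpec:
    """Conditions for a synthetic reference recording."""

    arena: Arena = field(default_factory=Arena)
    spots: list = field(default_factory=list)
    n_agents: int = 1
    duration: float = 3600.0
    dt: float = 1.0                       # recording interval, s
    kappa: float = 6.3                    # turning concentration
    speed_model: SpeedModel = field(default_factory=SpeedModel)
    wall_bias: bool = True                # wall-dwell fixture (see module docs)
    wall_bias_distance: float = 0.05      # m, width of the wall band
    wall_bias_kappa: float = 20.0         # concentration while wall-following
    wall_bias_tilt: float = 0.4           # rad, max interior tilt at the wall

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("ReferenceSpec.n_agents must be >= 1")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("ReferenceSpec.duration and dt must be > 0")
        if self.kappa < 0:
            raise ValueError("ReferenceSpec.kappa must be >= 0")
        for spot in self.spots:
            spot.validate_inside(self.arena)


#: world direction pointing from each wall into the arena interior
_INTERIOR_NORMAL = {"north": -0.5 * math.pi, "east": math.pi,
                    "south": 0.5 * math.pi, "west": 0.0}


def _wall_following_target(heading: float, d: float, wall: str,
                           spec: ReferenceSpec) -> float:
    """Body-frame mean turn while wall-following: along the wall direction
    closest to the current heading, tilted towards the interior by up to
    ``wall_bias_tilt`` radians as the wall gets closer."""
    d1, d2 = wall_following_directions(wall, heading)
    parallel_body = d1 if abs(d1) <= abs(d2) else d2
    normal_body = wrap_angle(_INTERIOR_NORMAL[wall] - heading)
    tilt = spec.wall_bias_tilt * (1.0 - d / spec.wall_bias_distance)
    sign = 1.0 if wrap_angle(normal_body - parallel_body) >= 0 else -1.0
    return float(wrap_angle(parallel_body + sign * tilt))


def generate_reference(spec: ReferenceSpec, seed: int) -> TrajectorySet:
    """Correlated-random-walk trajectories recorded every ``spec.dt``."""
    rng = np.random.default_rng(seed)
    heterogeneous = len(spec.spots) > 0
    centre = spec.arena.centre
    states = []
    for _ in range(spec.n_agents):
        r = RELEASE_RADIUS * math.sqrt(rng.random())
        phi = rng.uniform(-math.pi, math.pi)
        pos = centre + r * np.array([math.cos(phi), math.sin(phi)])
        states.append(AgentState(pos, rng.uniform(-math.pi, math.pi), 0.0))

    n_steps = int(round(spec.duration / spec.dt))
    frames = [np.array([s.position for s in states])]
    times = [0.0]
    for k in range(n_steps):
        new_states = []
        for st in states:
            if heterogeneous:
                regime = ("under_spot" if under_spot(st.position, spec.spots)[0]
                          else "outside_spot")
            else:
                regime = "homogeneous"
            v = spec.speed_model.sample(regime, rng)
            mu = 0.0
            kappa = spec.kappa
            if spec.wall_bias:
                d, wall = distance_to_nearest_wall(st.position, spec.arena)
                if d < spec.wall_bias_distance:
                    mu = _wall_following_target(st.heading, d, wall, spec)
                    kappa = spec.wall_bias_kappa
            dtheta = float(wrap_angle(mu + rng.vonmises(0.0, kappa)))
            new_states.append(step(st, dtheta, v, spec.dt, spec.arena))
        states = new_states
        frames.append(np.array([s.position for s in states]))
        times.append((k + 1) * spec.dt)

    return TrajectorySet(np.array(times), np.stack(frames),
                         np.arange(spec.n_agents))
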