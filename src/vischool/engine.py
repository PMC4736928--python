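"""Simulation engine: perception -> decision -> sampling -> kinematics.

All agents are updated synchronously: percepts for step t are computed
from the time-t states of every agent, then all positions advance
together.  A single seeded RNG stream drives the whole run with a fixed
draw order (agents in id order, speed draw then direction draw), so a run
is bit-reproducible from its configuration and seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .arena import (AgentState, Arena, SpeedModel, Spot,
                    distance_to_nearest_wall, step, under_spot,
                    wall_following_directions)
from .decision import (BehaviourParams, baseline_pdf, direction_grid,
                       global_pdf, pdf_to_cdf, sample_direction,
                       select_weights, stimulus_mixture_pdf)
from .geometry import perceive

__all__ = ["RunConfig", "TrajectorySet", "initialize", "simulate"]

#: radius (m) of the central release disc where agents start
RELEASE_RADIUS = 0.10

_MAX_AGENTS = 10_000


@dataclass
class RunConfig:
    """Full description of one simulation run."""

    arena: Arena = field(default_factory=Arena)
    spots: list = field(default_factory=list)
    n_agents: int = 1
    duration: float = 3600.0
    params: BehaviourParams = field(default_factory=BehaviourParams)
    speed_model: SpeedModel = field(default_factory=SpeedModel)
    seed: int = 0
    record_interval: float = 1.0

    def __post_init__(self):
        if self.n_agents < 1:
            raise ValueError("RunConfig.n_agents must be >= 1")
        if self.duration <= 0:
            raise ValueError("RunConfig.duration must be > 0")
        n_steps = self.duration / self.params.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("RunConfig.duration must be an integral number of dt steps")
        spr = self.record_interval / self.params.dt
        if abs(spr - round(spr)) > 1e-9 or round(spr) < 1:
            raise ValueError("RunConfig.record_interval must be a positive multiple of dt")
        for spot in self.spots:
            spot.validate_inside(self.arena)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.params.dt))

    @property
    def steps_per_record(self) -> int:
        return int(round(self.record_interval / self.params.dt))


@dataclass
class TrajectorySet:
    """Per-agent position time series on a shared uniform time base."""

    times: np.ndarray                 # (T,) seconds
    positions: np.ndarray             # (T, n_agents, 2) metres
    agent_ids: np.ndarray             # (n_agents,) integer labels

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.agent_ids = np.asarray(self.agent_ids, dtype=int)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (T, n_agents, 2)")
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if self.positions.shape[1] != self.agent_ids.shape[0]:
            raise ValueError("agent_ids and positions disagree on agent count")

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def record_interval(self) -> float:
        if len(self.times) < 2:
            return float("nan")
        return float(self.times[1] - self.times[0])

    def track(self, agent_id: int) -> np.ndarray:
        """The (T, 2) position series of one agent."""
        idx = int(np.nonzero(self.agent_ids == agent_id)[0][0])
        return self.positions[:, idx, :]


def _pick_regime(position, spots: Sequence[Spot], heterogeneous: bool) -> str:
    if not heterogeneous:
        return "homogeneous"
    return "under_spot" if under_spot(position, spots)[0] else "outside_spot"


def initialize(config: RunConfig, rng: np.random.Generator) -> list[AgentState]:
    """Initial states: positions uniform in the central release disc
    (radius 0.10 m, mirroring the acclimatization arena), headings uniform
    in [-pi, pi), speeds drawn from the regime at the initial position."""
    if config.n_agents > _MAX_AGENTS:
        raise ValueError(f"n_agents exceeds {_MAX_AGENTS}")
    heterogeneous = len(config.spots) > 0
    centre = config.arena.centre
    states = []
    for _ in range(config.n_agents):
        r = RELEASE_RADIUS * math.sqrt(rng.random())
        phi = rng.uniform(-math.pi, math.pi)
        pos = centre + r * np.array([math.cos(phi), math.sin(phi)])
        heading = rng.uniform(-math.pi, math.pi)
        regime = _pick_regime(pos, config.spots, heterogeneous)
        speed = config.speed_model.sample(regime, rng)
        states.append(AgentState(pos, heading, speed))
    return states


def _decide_turn(i: int, states: Sequence[AgentState], config: RunConfig,
                 grid: np.ndarray, fish_enabled: bool, spots_enabled: bool,
                 u: float) -> float:
    """Body-frame turning angle for agent i, given the time-t states."""
    p = config.params
    st = states[i]
    d, wall = distance_to_nearest_wall(st.position, config.arena)
    wall_dirs = wall_following_directions(wall, st.heading) if d < p.d_wall else None
    f0 = baseline_pdf(d, wall_dirs, p, grid=grid)

    others = [s for j, s in enumerate(states) if j != i]
    percepts = perceive(st, others, config.spots, p)
    fish_p = [q for q in percepts if q.kind == "fish" and q.solid_angle > 0]
    spot_p = [q for q in percepts if q.kind == "spot" and q.solid_angle > 0]

    f_fish, a_tf = (stimulus_mixture_pdf(fish_p, p.kappa_fish, grid=grid)
                    if fish_p else (None, 0.0))
    f_spot, a_ts = (stimulus_mixture_pdf(spot_p, p.kappa_spot, grid=grid)
                    if spot_p else (None, 0.0))
    alpha_star, beta_star = select_weights(d, p, fish_enabled, spots_enabled)
    f = global_pdf(f0, f_fish, f_spot, a_tf, a_ts, alpha_star, beta_star)
    return float(sample_direction(pdf_to_cdf(f), u))


def simulate(config: RunConfig,
             on_step: Optional[Callable[[int, Sequence[AgentState]], None]] = None
             ) -> TrajectorySet:
    """Run the model and record positions every ``record_interval``.

    The trajectory includes the initial frame and the final one:
    duration/record_interval + 1 frames in total.  ``on_step`` (if given)
    is called after every state update with the step index and new states.
    """
    rng = np.random.default_rng(config.seed)
    states = initialize(config, rng)
    p = config.params
    grid = direction_grid(p.n_grid)
    fish_enabled = config.n_agents > 1
    spots_enabled = len(config.spots) > 0
    heterogeneous = spots_enabled

    spr = config.steps_per_record
    frames = [np.array([s.position for s in states])]
    times = [0.0]

    for k in range(config.n_steps):
        new_states = []
        for i in range(config.n_agents):
            regime = _pick_regime(states[i].position, config.spots, heterogeneous)
            v = config.speed_model.sample(regime, rng)
            u = rng.random()
            theta = _decide_turn(i, states, config, grid, fish_enabled,
                                 spots_enabled, u)
            new_states.append(step(states[i], theta, v, p.dt, config.arena))
        states = new_states
        if on_step is not None:
            on_step(k, states)
        if (k + 1) % spr == 0:
            frames.append(np.array([s.position for s in states]))
            times.append(((k + 1) // spr) * config.record_interval)

    return TrajectorySet(np.array(times), np.stack(frames),
                         np.arange(config.n_agents))
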