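"""Trajectory tables, configuration files, logging and seeding.

Trajectories travel as plain delimited text with the header
``time_s,agent_id,x_m,y_m`` — one row per agent per recorded frame, SI
units throughout.  Run configurations are YAML mappings; unspecified keys
take the fitted defaults, the fully resolved configuration is echoed to
the log, and an omitted seed is generated and stored so any run can be
replayed exactly.
"""
from __future__ import annotations

import csv
import logging
import math
import secrets
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .arena import Arena, SpeedModel, Spot
from .decision import BehaviourParams
from .engine import RunConfig, TrajectorySet
from .synthetic import ReferenceSpec

__all__ = [
    "TrajectoryParseError",
    "TrajectoryFormatError",
    "ConfigError",
    "read_trajectories",
    "write_trajectories",
    "load_config",
    "load_reference_spec",
]

logger = logging.getLogger("vischool")

_HEADER = ["time_s", "agent_id", "x_m", "y_m"]


class TrajectoryParseError(ValueError):
    """A trajectory table row could not be parsed."""


class TrajectoryFormatError(ValueError):
    """The table parsed but is not a valid trajectory set."""


class ConfigError(ValueError):
    """A configuration file is malformed or violates an invariant."""


def write_trajectories(trajs: TrajectorySet, path) -> None:
    """Write a trajectory table; floats use shortest round-trip repr, so
    write -> read is lossless."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for t_idx in range(trajs.n_frames):
            t = trajs.times[t_idx]
            for a_idx, agent in enumerate(trajs.agent_ids):
                x, y = trajs.positions[t_idx, a_idx]
                writer.writerow([repr(float(t)), int(agent),
                                 repr(float(x)), repr(float(y))])


def read_trajectories(path) -> TrajectorySet:
    """Parse a trajectory table back into a :class:`TrajectorySet`.

    Malformed rows raise :class:`TrajectoryParseError` naming the line;
    a non-uniform time base raises :class:`TrajectoryFormatError`.
    """
    path = Path(path)
    records: dict[int, dict[float, tuple[float, float]]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrajectoryParseError(f"{path}: empty file, missing header")
        if [h.strip() for h in header] != _HEADER:
            raise TrajectoryParseError(
                f"{path}, line 1: expected header {','.join(_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise TrajectoryParseError(
                    f"{path}, line {lineno}: expected 4 fields, got {len(row)}")
            try:
                t = float(row[0])
                agent = int(row[1])
                x, y = float(row[2]), float(row[3])
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"{path}, line {lineno}: {exc}") from exc
            records.setdefault(agent, {})
            if t in records[agent]:
                raise TrajectoryFormatError(
                    f"{path}, line {lineno}: duplicate time {t} for agent {agent}")
            records[agent][t] = (x, y)

    if not records:
        return TrajectorySet(np.empty(0), np.empty((0, 0, 2)), np.empty(0, dtype=int))

    agent_ids = sorted(records)
    times = sorted(records[agent_ids[0]])
    for agent in agent_ids:
        if sorted(records[agent]) != times:
            raise TrajectoryFormatError(
                f"{path}: agents do not share a common time base")
    if len(times) >= 3:
        steps = np.diff(times)
        if np.max(steps) - np.min(steps) > 1e-6 * max(np.max(np.abs(times)), 1.0):
            raise TrajectoryFormatError(f"{path}: non-uniform time base")
    positions = np.array([[records[a][t] for a in agent_ids] for t in times])
    return TrajectorySet(np.array(times), positions, np.array(agent_ids))


_RUN_KEYS = {"arena_side", "spots", "n_agents", "duration_s", "dt_s",
             "record_interval_s", "seed", "speed", "behaviour"}
_BEHAVIOUR_KEYS = {"kappa0", "kappa_wall", "kappa_fish", "kappa_spot",
                   "alpha0", "alpha_wall", "beta0", "beta_wall",
                   "w_fish", "w_spot", "d_wall", "fov_deg", "n_grid"}
_SPOT_KEYS = {"x", "y", "radius", "height"}
_REF_KEYS = {"arena_side", "spots", "n_agents", "duration_s", "dt_s", "seed",
             "kappa", "speed", "wall_bias", "wall_bias_distance",
             "wall_bias_kappa"}


def _load_yaml_mapping(path) -> dict:
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a key-value mapping at top level")
    return doc


def _check_keys(doc: dict, valid: set, context: str) -> None:
    unknown = set(doc) - valid
    if unknown:
        raise ConfigError(
            f"unknown {context} key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(valid)}")


def _parse_spots(raw, arena: Arena) -> list[Spot]:
    spots = []
    for entry in raw or []:
        _check_keys(entry, _SPOT_KEYS, "spot")
        spot = Spot((float(entry["x"]), float(entry["y"])),
                    radius=float(entry.get("radius", 0.1)),
                    height=float(entry.get("height", 0.05)))
        spot.validate_inside(arena)
        spots.append(spot)
    return spots


def _parse_speed(raw) -> SpeedModel:
    model = SpeedModel()
    for regime, spec in (raw or {}).items():
        if regime not in model.regimes:
            raise ConfigError(
                f"unknown speed regime {regime!r}; valid: {sorted(model.regimes)}")
        _check_keys(spec, {"mean", "sd"}, f"speed.{regime}")
        model.regimes[regime] = (float(spec["mean"]), float(spec["sd"]))
    return model


def _resolve_seed(doc: dict) -> int:
    seed = doc.get("seed")
    if seed is None:
        seed = secrets.randbelow(2**31)
        logger.info("no seed in config; generated seed %d", seed)
    return int(seed)


def load_config(path) -> RunConfig:
    """Load a simulation run configuration; unspecified keys take the
    fitted defaults.  The resolved configuration is echoed to the log."""
    doc = _load_yaml_mapping(path)
    _check_keys(doc, _RUN_KEYS, "config")
    arena = Arena(side=float(doc.get("arena_side", 1.20)))
    behaviour = dict(doc.get("behaviour") or {})
    _check_keys(behaviour, _BEHAVIOUR_KEYS, "behaviour")
    if "fov_deg" in behaviour:
        behaviour["fov"] = math.radians(behaviour.pop("fov_deg"))
    if "dt_s" in doc:
        behaviour["dt"] = float(doc["dt_s"])
    try:
        params = BehaviourParams(**behaviour)
        config = RunConfig(
            arena=arena,
            spots=_parse_spots(doc.get("spots"), arena),
            n_agents=int(doc.get("n_agents", 1)),
            duration=float(doc.get("duration_s", 3600.0)),
            params=params,
            speed_model=_parse_speed(doc.get("speed")),
            seed=_resolve_seed(doc),
            record_interval=float(doc.get("record_interval_s", 1.0)),
        )
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    logger.info("resolved run config: %s", _config_summary(config))
    return config


def load_reference_spec(path) -> tuple[ReferenceSpec, int]:
    """Load a synthetic-reference spec; returns (spec, seed)."""
    doc = _load_yaml_mapping(path)
    _check_keys(doc, _REF_KEYS, "reference config")
    arena = Arena(side=float(doc.get("arena_side", 1.20)))
    try:
        spec = ReferenceSpec(
            arena=arena,
            spots=_parse_spots(doc.get("spots"), arena),
            n_agents=int(doc.get("n_agents", 1)),
            duration=float(doc.get("duration_s", 3600.0)),
            dt=float(doc.get("dt_s", 1.0)),
            kappa=float(doc.get("kappa", 6.3)),
            speed_model=_parse_speed(doc.get("speed")),
            wall_bias=bool(doc.get("wall_bias", False)),
            wall_bias_distance=float(doc.get("wall_bias_distance", 0.05)),
            wall_bias_kappa=float(doc.get("wall_bias_kappa", 20.0)),
        )
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    seed = _resolve_seed(doc)
    logger.info("resolved reference spec: %s, seed=%d", spec, seed)
    return spec, seed


def _config_summary(config: RunConfig) -> str:
    d = {
        "arena_side": config.arena.side,
        "spots": [asdict(s) for s in config.spots],
        "n_agents": config.n_agents,
        "duration_s": config.duration,
        "dt_s": config.params.dt,
        "record_interval_s": config.record_interval,
        "seed": config.seed,
        "behaviour": asdict(config.params),
        "speed": config.speed_model.regimes,
    }
    return repr(d)
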