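"""Spherical visual-perception geometry.

Agents carry a cyclopean visual sensor: a spherical field of view of 270
degrees extending frontally and laterally, with an infinite perception
radius.  A stimulus (a neighbouring fish, modelled as a six-vertex solid
of length 3.5 cm, width 1 cm and height 1 cm, or a floating disc) is
measured by the *solid angle* its projection captures on a unit sphere
centred on the observer's head.  The projected outline is reduced to its
four extremal points, which form a spherical quadrilateral; the
quadrilateral is split into two spherical triangles whose excesses are
computed with L'Huilier's theorem.

All azimuths are body-frame angles: 0 points along the current heading and
positive angles are to the left (counter-clockwise seen from above).
Elevation 0 is the horizontal swimming plane, positive is up.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - annotations only, avoids an import cycle
    from .arena import AgentState, Spot
    from .decision import BehaviourParams

__all__ = [
    "DegenerateGeometryError",
    "InvalidTriangleError",
    "SpherePoint",
    "Percept",
    "BodyModel",
    "wrap_angle",
    "project_to_unit_sphere",
    "great_circle_arc",
    "spherical_triangle_solid_angle",
    "quad_solid_angle",
    "fish_body_vertices",
    "fish_extremal_quad",
    "spot_extremal_quad",
    "perceive",
]

_ELEVATION_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Observer and stimulus coincide or overlap; no direction is defined."""


class InvalidTriangleError(ValueError):
    """Arc lengths violate the spherical triangle inequalities."""


def wrap_angle(angle):
    """Wrap an angle (scalar or array, radians) to ``[-pi, pi)``."""
    return (angle + np.pi) % (2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class SpherePoint:
    """A direction on the observer's unit sphere.

    azimuth : body-frame angle in [-pi, pi), 0 = forward, positive left.
    elevation : angle above the horizontal plane, in [-pi/2, pi/2].
    """

    azimuth: float
    elevation: float

    def __post_init__(self):
        az = float(wrap_angle(self.azimuth))
        el = float(self.elevation)
        if abs(el) > math.pi / 2 + _ELEVATION_TOL:
            raise ValueError(f"elevation {el!r} outside [-pi/2, pi/2]")
        el = min(max(el, -math.pi / 2), math.pi / 2)
        object.__setattr__(self, "azimuth", az)
        object.__setattr__(self, "elevation", el)


@dataclass(frozen=True)
class Percept:
    """One perceived stimulus: its kind, body-frame bearing of the centroid
    and the solid angle (steradians) captured by its extremities."""

    kind: str  # "fish" or "spot"
    bearing: float
    solid_angle: float
    source_id: int

    def __post_init__(self):
        if self.kind not in ("fish", "spot"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not 0.0 <= self.solid_angle < 2.0 * math.pi:
            raise ValueError(f"solid_angle {self.solid_angle!r} outside [0, 2*pi)")
        object.__setattr__(self, "bearing", float(wrap_angle(self.bearing)))


@dataclass(frozen=True)
class BodyModel:
    """Six-vertex fish body: a nose vertex at the head position, four corner
    vertices (±width/2 laterally, ±height/2 vertically) placed 40% of the
    body length behind the nose, and a tail vertex a full length behind."""

    length: float = 0.035
    width: float = 0.01
    height: float = 0.01

    def __post_init__(self):
        for name in ("length", "width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BodyModel.{name} must be > 0")


# fraction of the body length between the nose and the widest section
_CORNER_FRACTION = 0.4


def project_to_unit_sphere(point, observer_position, observer_heading: float) -> SpherePoint:
    """Project a 3D world point onto the observer's unit sphere.

    ``point`` and ``observer_position`` are length-3 (x, y, z) positions in
    metres (length-2 inputs are lifted to the z=0 swimming plane).  The
    returned azimuth is measured in the observer's body frame.  A point
    straight above/below the observer has an undefined azimuth; by
    convention 0 is returned there.
    """
    p = _as_xyz(point)
    o = _as_xyz(observer_position)
    d = p - o
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise DegenerateGeometryError("point coincides with the observer")
    elevation = math.asin(min(max(d[2] / r, -1.0), 1.0))
    if math.hypot(d[0], d[1]) == 0.0:
        azimuth = 0.0  # pole convention
    else:
        azimuth = wrap_angle(math.atan2(d[1], d[0]) - observer_heading)
    return SpherePoint(azimuth, elevation)


def great_circle_arc(p1: SpherePoint, p2: SpherePoint) -> float:
    """Arc length (radians, in [0, pi]) of the great circle between two
    directions, via the spherical law of cosines on elevation/azimuth."""
    cos_a = math.sin(p1.elevation) * math.sin(p2.elevation) + math.cos(
        p1.elevation
    ) * math.cos(p2.elevation) * math.cos(p1.azimuth - p2.azimuth)
    return math.acos(min(max(cos_a, -1.0), 1.0))


def spherical_triangle_solid_angle(a: float, b: float, c: float) -> float:
    """Spherical excess E (= solid angle, sr) of a triangle with side arcs
    a, b, c, computed with L'Huilier's theorem:

        tan(E/4) = sqrt( tan(s/2) tan((s-a)/2) tan((s-b)/2) tan((s-c)/2) )

    with s the semi-perimeter (a+b+c)/2.
    """
    sides = (a, b, c)
    if any(x < -1e-12 for x in sides):
        raise InvalidTriangleError(f"negative arc length in {sides}")
    a, b, c = (max(x, 0.0) for x in sides)
    tol = 1e-9
    if a > b + c + tol or b > a + c + tol or c > a + b + tol:
        raise InvalidTriangleError(f"arcs {sides} violate the triangle inequality")
    if a + b + c >= 2.0 * math.pi - tol:
        raise InvalidTriangleError(f"perimeter of {sides} not below 2*pi")
    s = 0.5 * (a + b + c)
    prod = (
        math.tan(0.5 * s)
        * math.tan(0.5 * (s - a))
        * math.tan(0.5 * (s - b))
        * math.tan(0.5 * (s - c))
    )
    if prod <= 0.0:  # flat (degenerate) triangle up to rounding
        return 0.0
    return 4.0 * math.atan(math.sqrt(prod))


def quad_solid_angle(vertices: Sequence[SpherePoint]) -> float:
    """Solid angle (sr) of the spherical quadrilateral with the given ordered
    boundary, as the sum of the excesses of the two triangles obtained by
    splitting along the (v1, v3) diagonal.

    For a convex quad the result is invariant (to ~1e-9) under the choice of
    splitting diagonal.  Coincident vertices yield 0 with a warning.
    """
    if len(vertices) != 4:
        raise ValueError("quad_solid_angle expects exactly four vertices")
    v1, v2, v3, v4 = vertices
    pairs = [(v1, v2), (v1, v3), (v1, v4), (v2, v3), (v2, v4), (v3, v4)]
    if any(great_circle_arc(p, q) < 1e-12 for p, q in pairs):
        warnings.warn("coincident vertices: degenerate quad, solid angle 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    total = _triangle_excess(v1, v2, v3) + _triangle_excess(v1, v3, v4)
    # a convex stimulus seen from outside subtends at most a hemisphere;
    # near-contact geometry can make the split triangles overlap, so cap
    return min(total, 2.0 * math.pi)


def _triangle_excess(p: SpherePoint, q: SpherePoint, r: SpherePoint) -> float:
    a = great_circle_arc(q, r)
    b = great_circle_arc(p, r)
    c = great_circle_arc(p, q)
    return spherical_triangle_solid_angle(a, b, c)


def _as_xyz(point) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    if p.shape == (2,):
        return np.array([p[0], p[1], 0.0])
    if p.shape == (3,):
        return p
    raise ValueError(f"expected a 2D or 3D point, got shape {p.shape}")


def fish_body_vertices(position, heading: float, body: BodyModel) -> np.ndarray:
    """World coordinates, shape (6, 3), of a fish body's vertices.

    The head sits at ``position`` on the z=0 swimming plane; the body
    extends backwards along ``heading``.
    """
    x, y = float(position[0]), float(position[1])
    e = np.array([math.cos(heading), math.sin(heading), 0.0])  # forward
    n = np.array([-math.sin(heading), math.cos(heading), 0.0])  # left
    up = np.array([0.0, 0.0, 1.0])
    nose = np.array([x, y, 0.0])
    mid = nose - _CORNER_FRACTION * body.length * e
    hw, hh = 0.5 * body.width, 0.5 * body.height
    return np.stack([
        nose,
        mid + hw * n + hh * up,
        mid - hw * n + hh * up,
        mid + hw * n - hh * up,
        mid - hw * n - hh * up,
        nose - body.length * e,
    ])


def _observer_inside_body(observer_xy, target: "AgentState", body: BodyModel) -> bool:
    d = np.asarray(observer_xy, float) - np.asarray(target.position, float)
    c, s = math.cos(target.heading), math.sin(target.heading)
    along = c * d[0] + s * d[1]  # forward axis, nose at 0, tail at -length
    across = -s * d[0] + c * d[1]
    return (-body.length <= along <= 0.0) and (abs(across) <= 0.5 * body.width) \
        and (0.0 <= 0.5 * body.height)  # observer swims at z = 0, inside the box vertically


def _extremal_quad(points: np.ndarray, observer_xyz: np.ndarray,
                   observer_heading: float) -> list[SpherePoint]:
    """Project candidate boundary points and keep the four extremal ones
    (min/max azimuth, min/max elevation), ordered around the outline.

    Azimuth extremes are taken relative to the centroid direction so that
    stimuli straddling the ±pi branch cut are handled correctly.  The four
    selected indices are forced to be distinct.
    """
    rel = points - observer_xyz
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0.0):
        raise DegenerateGeometryError("stimulus vertex coincides with the observer")
    az = wrap_angle(np.arctan2(rel[:, 1], rel[:, 0]) - observer_heading)
    el = np.arcsin(np.clip(rel[:, 2] / r, -1.0, 1.0))
    centroid = np.mean(rel, axis=0)
    az_c = wrap_angle(math.atan2(centroid[1], centroid[0]) - observer_heading)
    rel_az = wrap_angle(az - az_c)

    used: list[int] = []
    for key in (rel_az, el, -rel_az, -el):  # right-most, lowest, left-most, highest
        order = np.argsort(key)
        idx = next(int(i) for i in order if int(i) not in used)
        used.append(idx)
    return [SpherePoint(float(az[i]), float(el[i])) for i in used]


def fish_extremal_quad(observer: "AgentState", target: "AgentState",
                       body: BodyModel) -> list[SpherePoint]:
    """Ordered quad of the four extremal projections of a target fish's six
    body vertices, as seen from the observer's head."""
    if _observer_inside_body(observer.position, target, body):
        raise DegenerateGeometryError("observer lies inside the target body volume")
    verts = fish_body_vertices(target.position, target.heading, body)
    obs = _as_xyz(observer.position)
    return _extremal_quad(verts, obs, observer.heading)


def spot_extremal_quad(observer: "AgentState", spot: "Spot") -> list[SpherePoint]:
    """Ordered quad of the four extremal rim points (nearest, rightmost,
    farthest, leftmost as seen from the observer) of a floating disc."""
    obs = _as_xyz(observer.position)
    cx, cy = float(spot.centre[0]), float(spot.centre[1])
    horiz = np.array([cx - obs[0], cy - obs[1]])
    dist = float(np.linalg.norm(horiz))
    if dist < 1e-12:
        u = np.array([math.cos(observer.heading), math.sin(observer.heading)])
    else:
        u = horiz / dist
    perp = np.array([-u[1], u[0]])
    rim2d = [
        np.array([cx, cy]) - spot.radius * u,   # nearest
        np.array([cx, cy]) - spot.radius * perp,
        np.array([cx, cy]) + spot.radius * u,   # farthest
        np.array([cx, cy]) + spot.radius * perp,
    ]
    rim = np.array([[p[0], p[1], spot.height] for p in rim2d])
    return _extremal_quad(rim, obs, observer.heading)


def perceive(focal: "AgentState", others: Sequence["AgentState"],
             spots: Sequence["Spot"], params: "BehaviourParams") -> list[Percept]:
    """All stimuli visible to the focal agent.

    A stimulus contributes one :class:`Percept` when the body-frame bearing
    of its centroid lies within the field of view (default 270 degrees, i.e.
    |bearing| <= 3*pi/4, boundary inclusive); stimuli in the rear blind zone
    are omitted entirely.  Solid angles come from the extremal-quad
    construction.
    """
    half_fov = 0.5 * params.fov
    obs = _as_xyz(focal.position)
    out: list[Percept] = []
    for i, other in enumerate(others):
        verts = fish_body_vertices(other.position, other.heading, params.body)
        centroid = verts.mean(axis=0)
        bearing = _bearing_of(centroid, obs, focal.heading)
        if abs(bearing) > half_fov:
            continue
        try:
            omega = quad_solid_angle(fish_extremal_quad(focal, other, params.body))
        except DegenerateGeometryError:
            # bodies may overlap; no solid angle is defined from inside a
            # target's volume, so the stimulus contributes nothing this step
            continue
        omega = min(omega, 2.0 * math.pi * (1.0 - 1e-12))
        out.append(Percept("fish", bearing, omega, i))
    for j, spot in enumerate(spots):
        centre = np.array([spot.centre[0], spot.centre[1], spot.height])
        bearing = _bearing_of(centre, obs, focal.heading)
        if abs(bearing) > half_fov:
            continue
        omega = quad_solid_angle(spot_extremal_quad(focal, spot))
        out.append(Percept("spot", bearing, omega, j))
    return out


def _bearing_of(point_xyz: np.ndarray, observer_xyz: np.ndarray, heading: float) -> float:
    d = point_xyz - observer_xyz
    if math.hypot(d[0], d[1]) == 0.0:
        return 0.0
    return float(wrap_angle(math.atan2(d[1], d[0]) - heading))
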