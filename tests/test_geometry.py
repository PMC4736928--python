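"""Spherical perception geometry: projections, arcs, solid angles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vischool import (AgentState, BehaviourParams, BodyModel, SpherePoint,
                      Spot, fish_body_vertices, fish_extremal_quad,
                      great_circle_arc, perceive, project_to_unit_sphere,
                      quad_solid_angle, spherical_triangle_solid_angle,
                      spot_extremal_quad, wrap_angle)
from vischool.geometry import DegenerateGeometryError, InvalidTriangleError


def _unit(p: SpherePoint) -> np.ndarray:
    return np.array([
        math.cos(p.elevation) * math.cos(p.azimuth),
        math.cos(p.elevation) * math.sin(p.azimuth),
        math.sin(p.elevation),
    ])


def girard_excess(p1, p2, p3):
    """Independent oracle: spherical excess as the sum of interior angles
    minus pi, angles computed from tangent vectors at each vertex."""
    verts = [_unit(p) for p in (p1, p2, p3)]
    total = 0.0
    for i in range(3):
        a, b, c = verts[i], verts[(i + 1) % 3], verts[(i + 2) % 3]
        tb = b - np.dot(a, b) * a
        tc = c - np.dot(a, c) * a
        cosang = np.dot(tb, tc) / (np.linalg.norm(tb) * np.linalg.norm(tc))
        total += math.acos(min(max(cosang, -1.0), 1.0))
    return total - math.pi


class TestProjection:
    def test_point_straight_ahead(self):
        p = project_to_unit_sphere([1.0, 0.0, 0.0], [0.0, 0.0, 0.0], 0.0)
        assert p.azimuth == pytest.approx(0.0)
        assert p.elevation == pytest.approx(0.0)

    def test_pole_convention(self):
        p = project_to_unit_sphere([0.0, 0.0, 1.0], [0.0, 0.0, 0.0], 1.2)
        assert p.azimuth == 0.0
        assert p.elevation == pytest.approx(math.pi / 2)

    def test_ahead_and_left(self):
        p = project_to_unit_sphere([1.0, 1.0, 0.0], [0.0, 0.0, 0.0], 0.0)
        assert p.azimuth == pytest.approx(math.pi / 4)

    def test_heading_rotates_azimuth(self):
        p = project_to_unit_sphere([0.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                                   math.pi / 2)
        assert p.azimuth == pytest.approx(0.0)

    def test_coincident_point_raises(self):
        with pytest.raises(DegenerateGeometryError):
            project_to_unit_sphere([0.5, 0.5, 0.0], [0.5, 0.5, 0.0], 0.0)


class TestGreatCircleArc:
    def test_identity(self):
        p = SpherePoint(0.3, 0.2)
        assert great_circle_arc(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal(self):
        a = SpherePoint(0.0, 0.0)
        b = SpherePoint(math.pi - 1e-15, 0.0)
        assert great_circle_arc(a, b) == pytest.approx(math.pi)

    def test_equatorial_quarter(self):
        assert great_circle_arc(SpherePoint(0, 0), SpherePoint(math.pi / 2, 0)
                                ) == pytest.approx(math.pi / 2)

    def test_same_meridian(self):
        # points with equal azimuth separated only in elevation
        assert great_circle_arc(SpherePoint(0.7, 0.1), SpherePoint(0.7, 0.5)
                                ) == pytest.approx(0.4)


class TestTriangleExcess:
    def test_octant(self):
        e = spherical_triangle_solid_angle(math.pi / 2, math.pi / 2, math.pi / 2)
        assert e == pytest.approx(math.pi / 2, abs=1e-12)

    def test_flat_triangle(self):
        assert spherical_triangle_solid_angle(0.3, 0.4, 0.7) == pytest.approx(
            0.0, abs=1e-9)

    def test_planar_limit(self):
        # tiny triangle: spherical excess ~ planar area of the flat triangle
        a = b = 1e-3
        c = math.sqrt(2) * 1e-3
        area = 0.5 * a * b
        e = spherical_triangle_solid_angle(a, b, c)
        assert e == pytest.approx(area, abs=1e-9)

    def test_invalid_triangle_rejected(self):
        with pytest.raises(InvalidTriangleError):
            spherical_triangle_solid_angle(2.0, 0.5, 0.5)

    def test_lhuilier_matches_girard_on_random_triangles(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            v = rng.normal(size=(3, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = [SpherePoint(math.atan2(y, x), math.asin(np.clip(z, -1, 1)))
                   for x, y, z in v]
            arcs = [great_circle_arc(pts[1], pts[2]),
                    great_circle_arc(pts[0], pts[2]),
                    great_circle_arc(pts[0], pts[1])]
            e = spherical_triangle_solid_angle(*arcs)
            assert e == pytest.approx(girard_excess(*pts), abs=1e-9)


class TestQuadSolidAngle:
    def test_quarter_sphere(self):
        # lune between azimuths 0 and pi/2, pole to pole: two octants; the
        # ordering puts the splitting diagonal on the equator
        quad = [SpherePoint(0.0, 0.0), SpherePoint(0.0, math.pi / 2),
                SpherePoint(math.pi / 2, 0.0), SpherePoint(0.0, -math.pi / 2)]
        assert quad_solid_angle(quad) == pytest.approx(math.pi, abs=1e-6)

    def test_diagonal_split_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            az0 = rng.uniform(-math.pi, math.pi)
            el0 = rng.uniform(-0.8, 0.8)
            daz = rng.uniform(0.05, 0.5)
            de = rng.uniform(0.05, 0.5)
            v1 = SpherePoint(az0 - daz, el0)
            v2 = SpherePoint(az0, el0 - de)
            v3 = SpherePoint(az0 + daz, el0)
            v4 = SpherePoint(az0, el0 + de)
            a = quad_solid_angle([v1, v2, v3, v4])
            b = quad_solid_angle([v2, v3, v4, v1])  # other diagonal
            assert a == pytest.approx(b, abs=1e-9)
            assert 0.0 <= a <= 2 * math.pi

    def test_degenerate_on_great_circle(self):
        quad = [SpherePoint(0.0, 0.0), SpherePoint(0.3, 0.0),
                SpherePoint(0.6, 0.0), SpherePoint(0.9, 0.0)]
        assert quad_solid_angle(quad) == pytest.approx(0.0, abs=1e-9)

    def test_coincident_vertices_warn(self):
        p = SpherePoint(0.1, 0.1)
        quad = [p, p, SpherePoint(0.4, 0.0), SpherePoint(0.2, 0.3)]
        with pytest.warns(RuntimeWarning):
            assert quad_solid_angle(quad) == 0.0


class TestFishQuad:
    def setup_method(self):
        self.body = BodyModel()

    def test_broadside_symmetric_about_zero(self):
        observer = AgentState([0.0, 0.0], 0.0, 0.0)
        # target centred straight ahead, running left-right (broadside);
        # the body extends behind the head, so the head sits at -L/2
        target = AgentState([0.5, -0.5 * self.body.length], -math.pi / 2, 0.0)
        quad = fish_extremal_quad(observer, target, self.body)
        azs = sorted(p.azimuth for p in quad)
        assert azs[0] == pytest.approx(-azs[-1], abs=1e-6)

    def test_solid_angle_decreases_with_distance(self):
        observer = AgentState([0.0, 0.0], 0.0, 0.0)
        omegas = []
        for dist in (0.2, 0.4, 0.8, 1.6):
            target = AgentState([dist, 0.0], math.pi / 2, 0.0)
            omegas.append(quad_solid_angle(
                fish_extremal_quad(observer, target, self.body)))
        assert all(a > b for a, b in zip(omegas, omegas[1:]))

    def test_aspect_changes_solid_angle(self):
        observer = AgentState([0.0, 0.0], 0.0, 0.0)
        broadside = AgentState([0.4, 0.0], math.pi / 2, 0.0)
        head_on = AgentState([0.4, 0.0], math.pi, 0.0)
        om_b = quad_solid_angle(fish_extremal_quad(observer, broadside, self.body))
        om_h = quad_solid_angle(fish_extremal_quad(observer, head_on, self.body))
        assert om_b != pytest.approx(om_h, rel=0.05)
        assert om_b > om_h  # more flank visible broadside

    def test_observer_inside_body_raises(self):
        observer = AgentState([0.49, 0.5], 0.0, 0.0)
        target = AgentState([0.5, 0.5], 0.0, 0.0)
        with pytest.raises(DegenerateGeometryError):
            fish_extremal_quad(observer, target, self.body)

    def test_body_vertices_extents(self):
        verts = fish_body_vertices([0.2, 0.3], 0.0, self.body)
        assert verts.shape == (6, 3)
        assert verts[:, 0].max() == pytest.approx(0.2)        # nose
        assert verts[:, 0].min() == pytest.approx(0.2 - 0.035)  # tail
        assert np.ptp(verts[:, 1]) == pytest.approx(0.01)
        assert np.ptp(verts[:, 2]) == pytest.approx(0.01)


class TestSpotQuad:
    def test_beneath_centre_symmetric(self):
        spot = Spot((0.6, 0.6))
        observer = AgentState([0.6, 0.6], 0.3, 0.0)
        quad = spot_extremal_quad(observer, spot)
        omega = quad_solid_angle(quad)
        assert omega > 0.0
        els = [p.elevation for p in quad]
        assert max(els) == pytest.approx(min(els), abs=1e-9)

    def test_bounded_by_analytic_cap(self):
        # on-axis disc cap: 2*pi*(1 - h/sqrt(h^2+R^2)) ~ 3.473 sr
        spot = Spot((0.6, 0.6))
        cap = 2 * math.pi * (1 - spot.height / math.hypot(spot.height, spot.radius))
        observer = AgentState([0.6, 0.6], 0.0, 0.0)
        omega = quad_solid_angle(spot_extremal_quad(observer, spot))
        assert 0.0 < omega <= cap
        assert cap == pytest.approx(3.473, abs=5e-3)

    def test_solid_angle_decreases_with_distance(self):
        spot = Spot((0.6, 0.6))
        omegas = []
        for dist in (0.15, 0.3, 0.6, 1.2):
            observer = AgentState([0.6 + dist, 0.6], 0.0, 0.0)
            omegas.append(quad_solid_angle(spot_extremal_quad(observer, spot)))
        assert all(a > b for a, b in zip(omegas, omegas[1:]))


class TestPerceive:
    def setup_method(self):
        self.params = BehaviourParams()

    def test_empty_scene(self):
        focal = AgentState([0.6, 0.6], 0.0, 0.0)
        assert perceive(focal, [], [], self.params) == []

    def test_single_fish_ahead(self):
        focal = AgentState([0.1, 0.6], 0.0, 0.0)
        other = AgentState([0.6, 0.6], 0.0, 0.0)
        percepts = perceive(focal, [other], [], self.params)
        assert len(percepts) == 1
        p = percepts[0]
        assert p.kind == "fish"
        assert p.bearing == pytest.approx(0.0, abs=1e-6)
        assert p.solid_angle > 0.0

    def test_rear_blind_zone_excluded(self):
        focal = AgentState([0.6, 0.6], 0.0, 0.0)
        behind = AgentState([0.1, 0.6], 0.0, 0.0)
        assert perceive(focal, [behind], [], self.params) == []

    def test_fov_boundary_inclusive(self):
        focal = AgentState([0.6, 0.6], 0.0, 0.0)
        # place a spot centre exactly at 135 degrees
        ang = 0.75 * math.pi
        spot = Spot((0.6 + 0.3 * math.cos(ang), 0.6 + 0.3 * math.sin(ang)))
        percepts = perceive(focal, [], [spot], self.params)
        assert len(percepts) == 1

    @settings(max_examples=30, deadline=None)
    @given(rot=st.floats(-math.pi, math.pi),
           dx=st.floats(-0.3, 0.3), dy=st.floats(-0.3, 0.3))
    def test_rigid_motion_invariance(self, rot, dx, dy):
        params = self.params
        focal = AgentState([0.5, 0.5], 0.4, 0.0)
        other = AgentState([0.8, 0.6], -1.0, 0.0)
        spot = Spot((0.4, 0.8))
        base = perceive(focal, [other], [spot], params)

        c, s = math.cos(rot), math.sin(rot)
        R = np.array([[c, -s], [s, c]])
        shift = np.array([dx, dy])

        def move(state):
            return AgentState(R @ np.asarray(state.position) + shift,
                              state.heading + rot, state.speed)

        spot2 = Spot(tuple(R @ np.array(spot.centre) + shift))
        moved = perceive(move(focal), [move(other)], [spot2], params)
        assert len(moved) == len(base)
        for p, q in zip(base, moved):
            assert q.bearing == pytest.approx(p.bearing, abs=1e-9)
            assert q.solid_angle == pytest.approx(p.solid_angle, rel=1e-6, abs=1e-12)


def test_wrap_angle_range():
    angles = np.linspace(-10, 10, 1001)
    wrapped = wrap_angle(angles)
    assert np.all(wrapped >= -math.pi)
    assert np.all(wrapped < math.pi)
    np.testing.assert_allclose(np.cos(wrapped), np.cos(angles), atol=1e-12)
    np.testing.assert_allclose(np.sin(wrapped), np.sin(angles), atol=1e-12)
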