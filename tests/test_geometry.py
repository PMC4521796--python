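"""Spherical geometry of the retinal coordinate system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retmap import geometry as geo
from retmap.geometry import (
    CapWindow,
    GeometryError,
    OutOfWindowError,
    RetinalPoint,
    canonicalize,
    cap_boundary,
    great_circle_distance,
    max_centroid_eccentricity,
    perimeter_centroid,
    project,
    spherical_centroid,
    spherical_region_area,
    unproject,
)

ecc_st = st.floats(0, 60)
ang_st = st.floats(0, 360, exclude_max=True)


def cap_fraction(radius_deg, window_deg=60.0):
    """Closed-form window fraction of a circular cap about the fovea."""
    return (1 - np.cos(np.radians(radius_deg))) / (1 - np.cos(np.radians(window_deg)))


class TestProjection:
    @pytest.mark.parametrize(
        "ecc, ang, x, y",
        [
            (0, 0, 0, 0),
            (30, 90, 30, 0),
            (30, 0, 0, 30),
            (45, 180, 0, -45),
            (20, 270, -20, 0),
        ],
    )
    def test_known_points(self, ecc, ang, x, y):
        px, py = project(ecc, ang)
        assert px == pytest.approx(x, abs=1e-12)
        assert py == pytest.approx(y, abs=1e-12)

    def test_quarter_turn_chord(self):
        ax, ay = project(30, 0)
        bx, by = project(30, 90)
        assert np.hypot(ax - bx, ay - by) == pytest.approx(30 * np.sqrt(2))

    @given(ecc=ecc_st, ang=ang_st)
    @settings(max_examples=200, deadline=None)
    def test_radial_distance_preserved(self, ecc, ang):
        x, y = project(ecc, ang)
        assert np.hypot(x, y) == pytest.approx(ecc, abs=1e-9)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        ecc = 60 * np.sqrt(rng.uniform(size=1000))
        ang = rng.uniform(0, 360, size=1000)
        e2, a2 = unproject(*project(ecc, ang))
        assert np.max(np.abs(e2 - ecc)) < 1e-9
        dang = np.abs((a2 - ang + 180) % 360 - 180)
        assert np.max(dang) < 1e-9

    def test_unproject_outside_window_raises(self, window):
        with pytest.raises(OutOfWindowError):
            unproject(50.0, 40.0, window)


class TestGreatCircle:
    def test_distance_from_fovea_equals_eccentricity(self):
        for ang in (0, 45, 123, 300):
            assert great_circle_distance(0, 0, 30, ang) == pytest.approx(30)

    def test_same_meridian_through_pole(self):
        assert great_circle_distance(30, 0, 30, 180) == pytest.approx(60)

    def test_dot_product_oracle(self):
        # arccos(cos^2 30 + sin^2 30 cos 90) = arccos(0.75)
        expected = np.degrees(np.arccos(0.75))
        assert great_circle_distance(30, 0, 30, 90) == pytest.approx(expected)

    @given(e1=ecc_st, a1=ang_st, e2=ecc_st, a2=ang_st, e3=ecc_st, a3=ang_st)
    @settings(max_examples=100, deadline=None)
    def test_metric_properties(self, e1, a1, e2, a2, e3, a3):
        dab = great_circle_distance(e1, a1, e2, a2)
        dba = great_circle_distance(e2, a2, e1, a1)
        assert dab == pytest.approx(dba, abs=1e-9)
        dac = great_circle_distance(e1, a1, e3, a3)
        dbc = great_circle_distance(e2, a2, e3, a3)
        assert dac <= dab + dbc + 1e-9

    @given(e1=ecc_st, a1=ang_st, e2=ecc_st, a2=ang_st)
    @settings(max_examples=200, deadline=None)
    def test_projected_euclidean_upper_bounds_great_circle(self, e1, a1, e2, a2):
        gc = great_circle_distance(e1, a1, e2, a2)
        (x1, y1), (x2, y2) = project(e1, a1), project(e2, a2)
        assert gc <= np.hypot(x1 - x2, y1 - y2) + 1e-9


class TestCanonicalize:
    @pytest.mark.parametrize(
        "ecc, ang, side, expected",
        [
            (20, 30, "left", 330.0),
            (20, 0, "left", 0.0),
            (20, 30, "right", 30.0),
        ],
    )
    def test_convention(self, ecc, ang, side, expected):
        e, a = canonicalize(ecc, ang, side)
        assert e == ecc
        assert a == pytest.approx(expected)

    @given(ecc=st.floats(0.1, 60), ang=ang_st)
    @settings(max_examples=100, deadline=None)
    def test_left_mirror_is_involution(self, ecc, ang):
        e1, a1 = canonicalize(ecc, ang, "left")
        e2, a2 = canonicalize(e1, a1, "left")
        assert e2 == pytest.approx(ecc)
        wrapped = (a2 - ang + 180) % 360 - 180
        assert abs(wrapped) < 1e-9

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            canonicalize(10, 10, "binocular")


class TestSphericalArea:
    def test_full_window_fraction_is_one(self):
        ecc, ang = cap_boundary(0, 0, 60, 720)
        _, frac = spherical_region_area(ecc, ang)
        assert frac == pytest.approx(1.0, rel=1e-4)

    def test_cap_closed_form(self):
        ecc, ang = cap_boundary(0, 0, 30, 1440)
        _, frac = spherical_region_area(ecc, ang)
        assert frac == pytest.approx(cap_fraction(30), rel=1e-4)

    def test_irregular_polygon_matches_monte_carlo(self):
        # frozen oracle: rejection sampling of 1e6 uniform points on the
        # window against the densified boundary gave fraction 0.141226
        ev = np.array([10.0, 25, 40, 30, 15, 20])
        av = np.array([0.0, 40, 80, 160, 220, 300])
        _, frac = spherical_region_area(ev, av)
        assert frac == pytest.approx(0.141226, rel=0.005)

    def test_invariant_under_reflection_and_rotation(self):
        ev = np.array([10.0, 25, 40, 30, 15, 20])
        av = np.array([0.0, 40, 80, 160, 220, 300])
        _, frac = spherical_region_area(ev, av)
        em, am = canonicalize(ev, av, "left")
        _, frac_m = spherical_region_area(em[::-1], am[::-1])
        assert frac_m == pytest.approx(frac, rel=1e-6)
        _, frac_r = spherical_region_area(ev, (av + 77.7) % 360)
        assert frac_r == pytest.approx(frac, rel=1e-6)

    def test_degenerate_and_self_intersecting_rejected(self):
        with pytest.raises(GeometryError):
            spherical_region_area([10, 20], [0, 90])
        # bowtie
        with pytest.raises(GeometryError):
            spherical_region_area([10, 10, 10, 10], [0, 180, 90, 270])


class TestSphericalCentroid:
    def test_cap_centroid_at_center(self):
        ecc, ang = cap_boundary(20, 45, 10, 144)
        c = spherical_centroid(ecc, ang)
        assert c.eccentricity == pytest.approx(20, abs=0.01)
        assert c.polar_angle == pytest.approx(45, abs=0.01)

    def test_full_window_centroid_at_fovea(self):
        ecc, ang = cap_boundary(0, 0, 60, 720)
        c = spherical_centroid(ecc, ang)
        assert c.eccentricity < 0.05

    def test_irregular_region_matches_monte_carlo(self):
        # frozen oracle: mean unit vector over 1e6 uniform in-region samples
        # gave (10.7218, 101.555); agreement required within 0.2 deg
        ev = np.array([10.0, 25, 40, 30, 15, 20])
        av = np.array([0.0, 40, 80, 160, 220, 300])
        c = spherical_centroid(ev, av)
        d = great_circle_distance(c.eccentricity, c.polar_angle, 10.7218, 101.555)
        assert d < 0.2

    def test_perimeter_centroid_agrees_for_cap_differs_for_crescent(self):
        ecc, ang = cap_boundary(20, 45, 10, 144)
        pc = perimeter_centroid(ecc, ang)
        assert great_circle_distance(pc.eccentricity, pc.polar_angle, 20, 45) < 0.05
        ev = np.array([5.0, 30, 55, 30.0])
        av = np.array([0.0, 20, 0, 340.0])
        ac = spherical_centroid(ev, av)
        pc = perimeter_centroid(ev, av)
        assert great_circle_distance(
            ac.eccentricity, ac.polar_angle, pc.eccentricity, pc.polar_angle
        ) > 0.2


class TestMaxCentroidEccentricity:
    def test_endpoints_agree(self):
        for mode in ("approx", "exact"):
            assert max_centroid_eccentricity(1.0, mode) == pytest.approx(0.0, abs=1e-9)
            assert max_centroid_eccentricity(0.0, mode) == pytest.approx(60.0)

    def test_quarter_area_values(self):
        assert max_centroid_eccentricity(0.25, "approx") == pytest.approx(30.0)
        expected = 60 - np.degrees(np.arccos(0.875))
        assert max_centroid_eccentricity(0.25, "exact") == pytest.approx(expected)

    def test_monotone_decreasing_and_bounded_gap(self):
        a = np.linspace(0, 1, 2001)
        approx = max_centroid_eccentricity(a, "approx")
        exact = max_centroid_eccentricity(a, "exact")
        assert np.all(np.diff(approx) <= 0)
        assert np.all(np.diff(exact) <= 1e-12)
        gap = np.abs(exact - approx)
        assert gap.max() < 2.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            max_centroid_eccentricity(1.2)


def test_retinal_point_normalizes_angle():
    assert RetinalPoint(10, 370).polar_angle == pytest.approx(10)
    assert RetinalPoint(0, 123).polar_angle == 0.0
    with pytest.raises(ValueError):
        RetinalPoint(-1, 0)


def test_window_properties():
    w = CapWindow()
    assert w.planar_area == pytest.approx(np.pi * 3600)
    assert w.solid_angle == pytest.approx(np.pi)  # 2*pi*(1-cos 60) = pi
    with pytest.raises(ValueError):
        CapWindow(radius=-5)
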