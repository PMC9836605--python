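"""Grid arithmetic: quadrant assignment, labels, bounds and polygons."""

import math
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gabreta.ceba_grid import (
    BASE_LAT_MIN,
    BASE_LON_MIN,
    DEFAULT_GRID,
    OutOfGridError,
    QUAD_LAT_MIN,
    QUAD_LON_MIN,
    Quadrant,
    QuadrantRef,
    format_label,
    parse_label,
    point_to_quadrant,
    quadrant_bounds,
    quadrant_centre,
    quadrant_polygon,
)

ORIGIN_LAT_MIN = DEFAULT_GRID.origin_lat_min  # 55°06'N in arc-minutes
ORIGIN_LON_MIN = DEFAULT_GRID.origin_lon_min  # 5°40'E


def brute_force_quadrant(lat: Fraction, lon: Fraction) -> QuadrantRef:
    """Independent boundary-scan oracle: test every quadrant box in a window.

    Bounds are recomputed here from the grid constants; containment is
    (south, north] x [west, east) in exact rationals, matching the
    north/west-closed convention.
    """
    lat_min, lon_min = lat * 60, lon * 60
    row_guess = int((ORIGIN_LAT_MIN - lat_min) / BASE_LAT_MIN)
    col_guess = int((lon_min - ORIGIN_LON_MIN) / BASE_LON_MIN)
    hits = []
    for row in range(max(row_guess - 1, 0), row_guess + 2):
        for col in range(max(col_guess - 1, 0), col_guess + 2):
            for qpos, (dr, dc) in {1: (0, 0), 2: (0, 1), 3: (1, 0), 4: (1, 1)}.items():
                north = ORIGIN_LAT_MIN - row * BASE_LAT_MIN - dr * QUAD_LAT_MIN
                west = ORIGIN_LON_MIN + col * BASE_LON_MIN + dc * QUAD_LON_MIN
                south, east = north - QUAD_LAT_MIN, west + QUAD_LON_MIN
                if south < lat_min <= north and west <= lon_min < east:
                    hits.append(QuadrantRef(row, col, Quadrant(qpos)))
    assert len(hits) == 1, f"point hit {len(hits)} boxes"
    return hits[0]


class TestPointToQuadrant:
    def test_matches_boundary_scan_oracle_on_random_points(self):
        rng = random.Random(1234)
        for _ in range(1000):
            lat = Fraction(rng.randint(46_000_000, 54_000_000), 1_000_000)
            lon = Fraction(rng.randint(6_000_000, 18_000_000), 1_000_000)
            assert point_to_quadrant(lat, lon) == brute_force_quadrant(lat, lon)

    def test_centre_maps_back_to_its_quadrant(self):
        rng = random.Random(9)
        for _ in range(200):
            q = QuadrantRef(rng.randint(0, 120), rng.randint(0, 90),
                            Quadrant(rng.randint(1, 4)))
            lat, lon = quadrant_centre(q)
            assert point_to_quadrant(lat, lon) == q

    def test_shared_meridian_belongs_to_eastern_quadrant(self):
        q = QuadrantRef(69, 45, Quadrant.NW)
        south, west, north, east = quadrant_bounds(q)
        lat_mid = (south + north) / 2
        # the NW quadrant's east edge is the NE quadrant's west edge
        assert point_to_quadrant(lat_mid, east) == QuadrantRef(69, 45, Quadrant.NE)
        # and the west edge belongs to this quadrant (west-closed)
        assert point_to_quadrant(lat_mid, west) == q

    def test_shared_parallel_belongs_to_northern_quadrant(self):
        q = QuadrantRef(69, 45, Quadrant.NW)
        south, west, north, east = quadrant_bounds(q)
        lon_mid = (west + east) / 2
        assert point_to_quadrant(south, lon_mid) == QuadrantRef(69, 45, Quadrant.SW)
        assert point_to_quadrant(north, lon_mid) == q  # north-closed

    def test_north_of_origin_is_out_of_grid(self):
        with pytest.raises(OutOfGridError):
            point_to_quadrant(56.0, 13.0)
        with pytest.raises(OutOfGridError):
            point_to_quadrant(49.0, 5.0)


class TestLabels:
    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 99), st.integers(0, 99), st.integers(1, 4))
    def test_parse_format_round_trip(self, row, col, qpos):
        q = QuadrantRef(row, col, Quadrant(qpos))
        assert parse_label(format_label(q)) == q

    def test_convention_example(self):
        assert format_label(QuadrantRef(69, 45, Quadrant.SW)) == "6945/3"
        assert parse_label("6945/3") == QuadrantRef(69, 45, Quadrant.SW)

    @pytest.mark.parametrize("bad", ["6945/5", "6945", "69/3", "abcd/1", "6945/0"])
    def test_malformed_labels_raise(self, bad):
        with pytest.raises(ValueError):
            parse_label(bad)


class TestBoundsAndPolygons:
    def test_extent_is_exact(self):
        q = QuadrantRef(69, 45, Quadrant.SE)
        south, west, north, east = quadrant_bounds(q)
        assert north - south == Fraction(3, 60)
        assert east - west == Fraction(5, 60)

    def test_nw_quadrant_shares_base_cell_corner(self):
        base_north = DEFAULT_GRID.origin_lat - 12 * Fraction(6, 60)
        base_west = DEFAULT_GRID.origin_lon + 7 * Fraction(10, 60)
        _, west, north, _ = quadrant_bounds(QuadrantRef(12, 7, Quadrant.NW))
        assert north == base_north and west == base_west

    def test_adjacent_quadrants_share_one_edge_no_overlap(self):
        a = quadrant_bounds(QuadrantRef(10, 10, Quadrant.NW))
        b = quadrant_bounds(QuadrantRef(10, 10, Quadrant.NE))
        assert a[3] == b[1]  # a.east == b.west
        assert a[0] == b[0] and a[2] == b[2]
        c = quadrant_bounds(QuadrantRef(10, 10, Quadrant.SW))
        assert a[0] == c[2]  # a.south == c.north
        # zero overlap area between any distinct pair in the base cell
        quads = [quadrant_bounds(QuadrantRef(10, 10, Quadrant(k))) for k in range(1, 5)]
        for i in range(4):
            for j in range(i + 1, 4):
                (s1, w1, n1, e1), (s2, w2, n2, e2) = quads[i], quads[j]
                lat_overlap = max(Fraction(0), min(n1, n2) - max(s1, s2))
                lon_overlap = max(Fraction(0), min(e1, e2) - max(w1, w2))
                assert lat_overlap * lon_overlap == 0

    def test_base_cell_is_tiled_exactly(self):
        areas = sum(
            (quadrant_bounds(QuadrantRef(3, 4, Quadrant(k)))[2]
             - quadrant_bounds(QuadrantRef(3, 4, Quadrant(k)))[0])
            * (quadrant_bounds(QuadrantRef(3, 4, Quadrant(k)))[3]
               - quadrant_bounds(QuadrantRef(3, 4, Quadrant(k)))[1])
            for k in range(1, 5)
        )
        assert areas == Fraction(6, 60) * Fraction(10, 60)

    def test_polygon_ring_properties(self):
        q = QuadrantRef(50, 20, Quadrant.NE)
        ring = quadrant_polygon(q)
        assert len(ring) == 5 and ring[0] == ring[-1]
        lons = [p[0] for p in ring[:-1]]
        lats = [p[1] for p in ring[:-1]]
        area = (max(lons) - min(lons)) * (max(lats) - min(lats))
        assert area == pytest.approx(float(Fraction(3, 60) * Fraction(5, 60)))
        clat, clon = quadrant_centre(q)
        assert min(lons) < clon < max(lons) and min(lats) < clat < max(lats)

    def test_metric_size_at_49N(self):
        """Quadrants are ~5.5 km north-south and ~6.1 km east-west at 49°N."""
        earth_radius_km = 6371.0
        lat_km = float(Fraction(3, 60)) * math.pi / 180 * earth_radius_km
        lon_km = (
            float(Fraction(5, 60)) * math.pi / 180 * earth_radius_km
            * math.cos(math.radians(49))
        )
        assert lat_km == pytest.approx(5.5, rel=0.05)
        assert lon_km == pytest.approx(6.1, rel=0.05)


class TestPartition:
    def test_random_points_hit_exactly_one_box(self):
        """Quadrant boxes tile the plane: the scan oracle asserts a unique hit."""
        rng = random.Random(77)
        for _ in range(300):
            lat = Fraction(rng.randint(47_000, 53_000), 1_000)
            lon = Fraction(rng.randint(7_000, 17_000), 1_000)
            brute_force_quadrant(lat, lon)  # raises if hits != 1
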