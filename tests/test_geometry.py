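"""Projection, containment, buffering, and area checks against independent
oracles (Vincenty geodesic, brute-force crossing number, analytic areas)."""

import math

import numpy as np
import pytest
from shapely.affinity import rotate, scale, translate
from shapely.geometry import Point, Polygon, box

from grazetrack.geometry import (
    Zone,
    buffer_geometry,
    point_in_polygon,
    points_in_polygon,
    polygon_area,
    polygon_from_wkt,
    to_geographic,
    to_planar,
    utm_zone_from_lon,
    zones_from_geojson,
    zones_to_geojson,
)


# --------------------------------------------------------------- oracles

def vincenty_distance(lat1, lon1, lat2, lon2):
    """Independent geodesic distance on the WGS84 ellipsoid (Vincenty inverse)."""
    a, f = 6378137.0, 1 / 298.257223563
    b = a * (1 - f)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    sU1, cU1, sU2, cU2 = math.sin(U1), math.cos(U1), math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(200):
        slam, clam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cU2 * slam, cU1 * sU2 - sU1 * cU2 * clam)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sU1 * sU2 + cU1 * cU2 * clam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cU1 * cU2 * slam / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        cos_2sm = cos_sigma - 2 * sU1 * sU2 / cos2_alpha if cos2_alpha else 0.0
        C = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < 1e-13:
            break
    u2 = cos2_alpha * (a**2 - b**2) / b**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    dsig = B * sin_sigma * (
        cos_2sm + B / 4 * (cos_sigma * (-1 + 2 * cos_2sm**2)
                           - B / 6 * cos_2sm * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sm**2))
    )
    return b * A * (sigma - dsig)


def crossing_number_inside(px, py, xs, ys):
    """Brute-force even-odd (crossing number) point-in-polygon test."""
    n = len(xs)
    inside = False
    for i in range(n):
        x1, y1 = xs[i], ys[i]
        x2, y2 = xs[(i + 1) % n], ys[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def random_simple_polygon(rng, n_vertices):
    """Star-shaped (hence simple) polygon with random radii — can be concave."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(2.0, 10.0, n_vertices)
    return Polygon(zip(radii * np.cos(angles), radii * np.sin(angles)))


# ------------------------------------------------------------- projection

def test_utm_round_trip_recovers_coordinates():
    rng = np.random.default_rng(0)
    lats = rng.uniform(-80, 80, 30)
    lons = rng.uniform(-179, 179, 30)
    for lat, lon in zip(lats, lons):
        x, y = to_planar(lat, lon)
        la, lo = to_geographic(x, y, zone=utm_zone_from_lon(lon), south=lat < 0)
        assert abs(la - lat) <= 1e-6
        assert abs(lo - lon) <= 1e-6


def test_planar_distance_matches_geodesic_oracle():
    # pairs ~100 m apart at the study site's latitude band
    rng = np.random.default_rng(1)
    for _ in range(20):
        lat1 = rng.uniform(25, 45)
        lon1 = rng.uniform(-90, -80)
        brg = rng.uniform(0, 2 * np.pi)
        lat2 = lat1 + 0.0009 * math.cos(brg)
        lon2 = lon1 + 0.0009 * math.sin(brg) / math.cos(math.radians(lat1))
        x1, y1 = to_planar(lat1, lon1, zone_spec=utm_zone_from_lon(lon1))
        x2, y2 = to_planar(lat2, lon2, zone_spec=utm_zone_from_lon(lon1))
        planar = math.hypot(x2 - x1, y2 - y1)
        geodesic = vincenty_distance(lat1, lon1, lat2, lon2)
        assert planar == pytest.approx(geodesic, rel=1e-3)


def test_local_frame_passthrough():
    x = np.array([1.0, 2.0])
    y = np.array([3.0, 4.0])
    ox, oy = to_planar(x, y, zone_spec="local")
    np.testing.assert_array_equal(ox, x)
    np.testing.assert_array_equal(oy, y)


def test_polar_latitudes_rejected():
    with pytest.raises(ValueError):
        to_planar(85.1, 0.0)


# ------------------------------------------------------------ containment

def test_point_in_polygon_basics():
    sq = box(0, 0, 1, 1)
    assert point_in_polygon((0.5, 0.5), sq)
    assert point_in_polygon((0.0, 0.0), sq)  # vertex: closed convention
    assert point_in_polygon((0.5, 0.0), sq)  # edge
    assert not point_in_polygon((2.0, 2.0), sq)
    c_shape = Polygon([(0, 0), (4, 0), (4, 4), (0, 4), (0, 3), (3, 3), (3, 1), (0, 1)])
    assert not point_in_polygon((1.0, 2.0), c_shape)  # in the notch
    assert point_in_polygon((3.5, 2.0), c_shape)


def test_degenerate_polygon_rejected():
    with pytest.raises(ValueError):
        point_in_polygon((0, 0), Polygon([(0, 0), (1, 1), (2, 2)]))


def test_containment_matches_crossing_number_oracle():
    rng = np.random.default_rng(2)
    for _ in range(25):
        poly = random_simple_polygon(rng, int(rng.integers(5, 50)))
        xs, ys = np.asarray(poly.exterior.xy[0][:-1]), np.asarray(poly.exterior.xy[1][:-1])
        px = rng.uniform(-11, 11, 400)
        py = rng.uniform(-11, 11, 400)
        got = points_in_polygon(px, py, poly)
        want = np.array([crossing_number_inside(a, b, xs, ys) for a, b in zip(px, py)])
        np.testing.assert_array_equal(got, want)


# --------------------------------------------------------------- buffering

def test_point_buffer_area_matches_circle():
    disc = buffer_geometry(Point(5, 5), 10.0, n_segments=64)
    assert disc.area == pytest.approx(math.pi * 100.0, rel=0.01)


def test_square_buffer_area_matches_analytic():
    sq = box(0, 0, 10, 10)
    for r in (2.0, 10.0):
        buf = buffer_geometry(sq, r)
        assert buf.area == pytest.approx(100 + 40 * r + math.pi * r**2, rel=0.01)


def test_buffer_contains_original_and_composes():
    g = box(0, 0, 5, 3)
    buf = buffer_geometry(g, 4.0)
    assert buf.contains(g)
    twice = buffer_geometry(buffer_geometry(g, 2.0), 2.0)
    once = buffer_geometry(g, 4.0)
    # one-shot r1+r2 covers the composed buffer up to arc discretization
    assert once.buffer(1e-6).contains(twice.buffer(-0.02))


def test_nonpositive_radius_rejected():
    with pytest.raises(ValueError):
        buffer_geometry(Point(0, 0), 0.0)


# ------------------------------------------------------------------- areas

def test_polygon_area_examples():
    assert polygon_area(box(0, 0, 1, 1)) == pytest.approx(1.0)
    # a 130 m x 100 m paddock is 1.3 ha
    assert polygon_area(box(0, 0, 130, 100)) == pytest.approx(13_000.0)
    fwd = Polygon([(0, 0), (2, 0), (2, 1), (0, 1)])
    rev = Polygon([(0, 1), (2, 1), (2, 0), (0, 0)])
    assert polygon_area(fwd) == polygon_area(rev)


def test_area_invariance_and_scaling():
    rng = np.random.default_rng(3)
    poly = random_simple_polygon(rng, 17)
    a0 = polygon_area(poly)
    assert polygon_area(translate(poly, 123.4, -56.7)) == pytest.approx(a0)
    assert polygon_area(rotate(poly, 37.0)) == pytest.approx(a0)
    assert polygon_area(scale(poly, 2.0, 2.0, origin=(0, 0))) == pytest.approx(4 * a0)


def test_too_few_vertices_rejected():
    with pytest.raises(ValueError):
        polygon_area([(0, 0), (1, 0)])


# ---------------------------------------------------------------- zone I/O

def test_zone_geojson_round_trip(tmp_path):
    zones = [
        Zone("shade", box(10, 10, 16, 16)).buffer(10.0),
        Zone("water", box(100, 5, 102, 7)).buffer(10.0),
    ]
    path = tmp_path / "zones.geojson"
    zones_to_geojson(zones, path)
    back = zones_from_geojson(path)
    assert [z.name for z in back] == ["shade", "water"]
    for z0, z1 in zip(zones, back):
        assert z1.buffered
        assert z1.area_m2 == pytest.approx(z0.area_m2, rel=1e-9)


def test_wkt_polygon_parse():
    poly = polygon_from_wkt("POLYGON ((0 0, 4 0, 4 4, 0 4, 0 0))")
    assert polygon_area(poly) == pytest.approx(16.0)
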