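"""Planar projection, polygon predicates, buffering, and areas.

All downstream spatial stages work in planar meters.  Real collar data in
WGS84 latitude/longitude is projected to UTM; synthetic data generated in a
local planar frame passes through untouched.  Polygon predicates use the
closed convention throughout: a point on the boundary counts as inside, so
fence-line fixes are never lost.

The UTM conversion is a from-first-principles transverse Mercator
(Krüger series on the WGS84 ellipsoid, central scale 0.9996), accurate to
well below a millimetre over a UTM zone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.wkt
from shapely.geometry import Point, Polygon, shape, mapping
from shapely.geometry.base import BaseGeometry

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_E0 = 500000.0  # false easting

_N = _F / (2.0 - _F)
_AA = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)
_ECC = math.sqrt(_F * (2.0 - _F))

# Krüger series coefficients (6th order in the third flattening n)
_ALPHA = np.array([
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180 - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440 + 281 * _N**5 / 630 - 1983433 * _N**6 / 1935360,
    61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880 + 167603 * _N**6 / 181440,
    49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
    34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
    212378941 * _N**6 / 319334400,
])
_BETA = np.array([
    _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360 - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105 - 1118711 * _N**6 / 3870720,
    17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480 + 5569 * _N**6 / 90720,
    4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
    4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
    20648693 * _N**6 / 638668800,
])


def utm_zone_from_lon(lon: float) -> int:
    """UTM zone number (1-60) containing longitude ``lon``."""
    return int((float(lon) + 180.0) // 6.0) % 60 + 1


def _central_meridian(zone: int) -> float:
    return zone * 6.0 - 183.0


def to_planar(lat, lon, zone_spec="auto"):
    """Project WGS84 coordinates to UTM easting/northing in meters.

    Parameters
    ----------
    lat, lon : array-like, degrees
    zone_spec : "auto" | "local" | int
        ``auto`` derives the UTM zone from the mean longitude; an int forces
        a zone; ``local`` means the inputs are already planar meters and are
        returned unchanged (the synthetic-data path).

    Returns
    -------
    (x, y) : ndarray pair, meters easting/northing.  For southern-hemisphere
    latitudes a 10,000,000 m false northing is applied, as in standard UTM.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if zone_spec == "local":
        # already-planar synthetic frame: passthrough, first arg -> first output
        return lat, lon
    if np.any(np.abs(lat) > 84.0):
        raise ValueError("latitude outside UTM validity (|lat| > 84 deg)")
    if zone_spec == "auto":
        zone = utm_zone_from_lon(float(np.mean(lon)))
    else:
        zone = int(zone_spec)
    lam0 = math.radians(_central_meridian(zone))

    phi = np.radians(lat)
    lam = np.radians(lon) - lam0

    sphi = np.sin(phi)
    t = np.sinh(np.arctanh(sphi) - _ECC * np.arctanh(_ECC * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.sqrt(t**2 + np.cos(lam) ** 2))

    j = np.arange(1, 7)[:, None]
    two_j_xi = 2.0 * j * np.atleast_1d(xi_p)[None, :]
    two_j_eta = 2.0 * j * np.atleast_1d(eta_p)[None, :]
    xi = np.atleast_1d(xi_p) + (_ALPHA[:, None] * np.sin(two_j_xi) * np.cosh(two_j_eta)).sum(axis=0)
    eta = np.atleast_1d(eta_p) + (_ALPHA[:, None] * np.cos(two_j_xi) * np.sinh(two_j_eta)).sum(axis=0)

    x = _E0 + _K0 * _AA * eta
    y = _K0 * _AA * xi
    south = np.atleast_1d(phi) < 0
    y = np.where(south, y + 10_000_000.0, y)
    if np.isscalar(lat) or lat.ndim == 0:
        return float(x[0]), float(y[0])
    return x, y


def to_geographic(x, y, zone: int, south: bool = False):
    """Inverse UTM: easting/northing (meters) back to WGS84 lat/lon degrees."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    lam0 = math.radians(_central_meridian(int(zone)))

    xi = (y - (10_000_000.0 if south else 0.0)) / (_K0 * _AA)
    eta = (x - _E0) / (_K0 * _AA)

    j = np.arange(1, 7)[:, None]
    two_j_xi = 2.0 * j * xi[None, :]
    two_j_eta = 2.0 * j * eta[None, :]
    xi_p = xi - (_BETA[:, None] * np.sin(two_j_xi) * np.cosh(two_j_eta)).sum(axis=0)
    eta_p = eta - (_BETA[:, None] * np.cos(two_j_xi) * np.sinh(two_j_eta)).sum(axis=0)

    # conformal latitude chi -> geodetic latitude by fixed-point iteration on
    # asinh(tan phi) = asinh(tan chi) + e*atanh(e*sin phi)
    chi = np.arcsin(np.clip(np.sin(xi_p) / np.cosh(eta_p), -1.0, 1.0))
    tan_chi = np.tan(chi)
    psi0 = np.arcsinh(tan_chi)
    phi = np.arctan(tan_chi)
    for _ in range(10):
        phi = np.arctan(np.sinh(psi0 + _ECC * np.arctanh(_ECC * np.sin(phi))))

    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    lat = np.degrees(phi)
    lon = np.degrees(lam + lam0)
    if lat.size == 1:
        return float(lat[0]), float(lon[0])
    return lat, lon


def _check_polygon(poly: Polygon) -> Polygon:
    if not isinstance(poly, Polygon):
        poly = Polygon(poly)
    if poly.is_empty or poly.area <= 0:
        raise ValueError("degenerate polygon (zero area)")
    return poly


def point_in_polygon(p, poly) -> bool:
    """Closed-convention containment: boundary points count as inside."""
    poly = _check_polygon(poly)
    if not isinstance(p, Point):
        p = Point(p)
    return bool(poly.covers(p))


def points_in_polygon(x, y, poly) -> np.ndarray:
    """Vectorized closed-convention containment test for fix arrays."""
    poly = _check_polygon(poly)
    pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return shapely.covers(poly, pts)


def buffer_geometry(geometry: BaseGeometry, radius_m: float, n_segments: int = 64) -> Polygon:
    """Outward round buffer, arcs discretized with ``n_segments`` vertices per
    full circle (the default 64 keeps circular areas within 1% of analytic)."""
    if radius_m <= 0:
        raise ValueError("buffer radius must be > 0")
    quad_segs = max(1, int(round(n_segments / 4)))
    return geometry.buffer(radius_m, quad_segs=quad_segs)


def polygon_area(poly) -> float:
    """Area in m^2 (holes subtracted); requires a simple polygon."""
    if not isinstance(poly, Polygon):
        coords = list(poly)
        if len(coords) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = Polygon(coords)
    if not poly.is_valid:
        raise ValueError("invalid (self-intersecting) polygon")
    a = poly.area
    if a <= 0:
        raise ValueError("degenerate polygon (zero area)")
    return float(a)


@dataclass
class Zone:
    """A named area of interest inside a paddock (shade, water, strips...)."""

    name: str
    geometry: Polygon
    buffered: bool = False
    area_m2: float = field(default=0.0)

    def __post_init__(self):
        if self.area_m2 == 0.0:
            self.area_m2 = polygon_area(self.geometry)

    def buffer(self, radius_m: float, n_segments: int = 64) -> "Zone":
        g = buffer_geometry(self.geometry, radius_m, n_segments)
        return Zone(name=self.name, geometry=g, buffered=True)


def zones_to_geojson(zones: list[Zone], path=None) -> str:
    """Serialize zones to a GeoJSON FeatureCollection (RFC 7946)."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(z.geometry),
                "properties": {"name": z.name, "buffered": z.buffered, "area_m2": z.area_m2},
            }
            for z in zones
        ],
    }
    text = json.dumps(fc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def zones_from_geojson(src) -> list[Zone]:
    """Read zones from a GeoJSON FeatureCollection (path or JSON string)."""
    if isinstance(src, str) and src.lstrip().startswith("{"):
        fc = json.loads(src)
    else:
        with open(src) as fh:
            fc = json.load(fh)
    zones = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        zones.append(
            Zone(
                name=props.get("name", "custom"),
                geometry=shape(feat["geometry"]),
                buffered=bool(props.get("buffered", False)),
            )
        )
    return zones


def polygon_from_wkt(text: str) -> Polygon:
    geom = shapely.wkt.loads(text)
    return _check_polygon(geom)
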