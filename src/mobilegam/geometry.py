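"""Spatial primitives for mobile-monitoring campaigns.

All computation is planar, in UTM meters.  A roadway is an ordered polyline
with a per-vertex elevation profile; an elevated structure (e.g. a bridge
ramping up to ~40 m above local ground) contributes through an *effective*
distance sqrt(h^2 + g^2), where g is the horizontal nearest distance and h
the interpolated deck height at the nearest point.

Shapely provides the point-to-polyline projection machinery; everything on
top of it (height interpolation, 10-m discretization, wind-sector
classification) lives here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point

__all__ = [
    "RoadSource",
    "SegmentedSource",
    "WindObservation",
    "nearest_distance",
    "effective_distance",
    "discretize_road",
    "wind_sector",
    "wind_sector_array",
    "read_roads_geojson",
    "write_roads_geojson",
]


@dataclass
class RoadSource:
    """A line source: ordered UTM vertices with a ground-clearance profile.

    Parameters
    ----------
    id : str
        Short identifier (e.g. ``"wb"``, ``"bqe"``).
    vertices : (n, 2) array-like
        Easting/northing in meters, at least two distinct points.
    elevation : (n,) array-like
        Height of the roadway deck above local ground at each vertex, in
        meters (>= 0).  All zeros for an at-grade road.
    counter_ids : list of str
        Traffic counters attached to this road (the subset actually used
        when building covariates is configured separately).
    """

    id: str
    vertices: np.ndarray
    elevation: np.ndarray
    counter_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError(f"road {self.id!r}: vertices must be (n, 2)")
        if len(self.vertices) < 2:
            raise ValueError(f"road {self.id!r}: need at least 2 vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0.0, axis=1)):
            raise ValueError(f"road {self.id!r}: consecutive vertices identical")
        if len(self.elevation) != len(self.vertices):
            raise ValueError(f"road {self.id!r}: elevation length != vertex length")
        if np.any(self.elevation < 0):
            raise ValueError(f"road {self.id!r}: elevation must be >= 0")

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)

    @property
    def vertex_arclengths(self) -> np.ndarray:
        """Cumulative arclength at each vertex (starts at 0)."""
        steps = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.vertex_arclengths[-1])

    @property
    def elevated(self) -> bool:
        return bool(np.any(self.elevation > 0))

    def height_at(self, arclength) -> np.ndarray:
        """Deck height above ground, linearly interpolated along the polyline."""
        return np.interp(arclength, self.vertex_arclengths, self.elevation)

    def point_at(self, arclength) -> np.ndarray:
        """Coordinates of the point at a given arclength (vectorized)."""
        s = np.atleast_1d(np.asarray(arclength, dtype=float))
        va = self.vertex_arclengths
        x = np.interp(s, va, self.vertices[:, 0])
        y = np.interp(s, va, self.vertices[:, 1])
        return np.column_stack([x, y])

    def tangent_bearing_at(self, arclength) -> np.ndarray:
        """Local road axis as a compass bearing in [0, 180) degrees."""
        s = np.atleast_1d(np.asarray(arclength, dtype=float))
        eps = 0.5
        p0 = self.point_at(np.clip(s - eps, 0, self.length))
        p1 = self.point_at(np.clip(s + eps, 0, self.length))
        d = p1 - p0
        bearing = np.degrees(np.arctan2(d[:, 0], d[:, 1])) % 180.0
        return bearing


@dataclass
class SegmentedSource:
    """A road chopped into consecutive arclength pieces (nominally 10 m).

    Each segment is treated as an individual source located at its arclength
    midpoint, carrying the interpolated deck height and a traffic weight
    ``e_j >= 0`` (vehicles/min apportioned to the segment).
    """

    road_id: str
    midpoints: np.ndarray      # (m, 2) UTM coordinates
    lengths: np.ndarray        # (m,) meters
    heights: np.ndarray        # (m,) meters above ground
    weights: np.ndarray        # (m,) e_j >= 0

    @property
    def n_segments(self) -> int:
        return len(self.lengths)

    def with_weights(self, weights) -> "SegmentedSource":
        w = np.asarray(weights, dtype=float)
        if w.shape != self.lengths.shape or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per segment")
        return SegmentedSource(self.road_id, self.midpoints, self.lengths,
                               self.heights, w)


@dataclass
class WindObservation:
    """One fixed-site wind reading: speed (m/s >= 0) and meteorological
    direction (degrees the wind blows FROM, [0, 360))."""

    timestamp: object
    speed: float
    direction: float

    def __post_init__(self):
        if self.speed < 0:
            raise ValueError("wind speed must be >= 0")
        self.direction = float(self.direction) % 360.0


def _check_road(road: RoadSource) -> None:
    if len(road.vertices) < 2:
        raise ValueError(f"road {road.id!r}: degenerate geometry (single vertex)")


def _project(points: np.ndarray, road: RoadSource):
    """Arclength of the nearest polyline point for each query point."""
    pts = shapely.points(points[:, 0], points[:, 1])
    return shapely.line_locate_point(road.line, pts)


def nearest_distance(point, road: RoadSource) -> float:
    """Shortest horizontal distance (m) from a point to the road polyline.

    The nearest point is the projection onto each segment clamped to its
    endpoints, minimized over segments (ties resolved by shapely's
    lowest-index convention, which does not affect the distance).
    """
    _check_road(road)
    p = np.asarray(point, dtype=float)
    return float(road.line.distance(Point(p[0], p[1])))


def nearest_distance_array(points, road: RoadSource) -> np.ndarray:
    _check_road(road)
    pts = np.asarray(points, dtype=float)
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    return shapely.distance(road.line, geoms)


def effective_distance(point, road: RoadSource) -> float:
    """Line-of-sight distance to an elevated roadway: sqrt(h^2 + g^2).

    g is the horizontal nearest distance and h the deck height linearly
    interpolated at the nearest polyline point.  For an at-grade road
    (h = 0 everywhere) this equals :func:`nearest_distance`.
    """
    return float(effective_distance_array(np.asarray(point, float)[None, :], road)[0])


def effective_distance_array(points, road: RoadSource) -> np.ndarray:
    _check_road(road)
    pts = np.asarray(points, dtype=float)
    g = nearest_distance_array(pts, road)
    s = _project(pts, road)
    h = road.height_at(s)
    return np.sqrt(g * g + h * h)


def discretize_road(road: RoadSource, segment_size: float = 10.0) -> SegmentedSource:
    """Partition the polyline arclength into consecutive pieces.

    Pieces have length ``segment_size`` except a possibly shorter final
    remainder, which is kept (not merged) so short roads stay representable.
    Traffic weights are initialised to zero and populated by the caller.
    """
    _check_road(road)
    if segment_size <= 0:
        raise ValueError("segment_size must be > 0")
    total = road.length
    n_full = int(np.floor(total / segment_size + 1e-12))
    bounds = np.arange(n_full + 1) * segment_size
    if total - bounds[-1] > 1e-9:
        bounds = np.append(bounds, total)
    else:
        bounds[-1] = total
    lengths = np.diff(bounds)
    mids = (bounds[:-1] + bounds[1:]) / 2.0
    return SegmentedSource(
        road_id=road.id,
        midpoints=road.point_at(mids),
        lengths=lengths,
        heights=np.asarray(road.height_at(mids), dtype=float),
        weights=np.zeros_like(lengths),
    )


def _angdiff(a, b):
    """Absolute angular difference in degrees, in [0, 180]."""
    d = np.abs((np.asarray(a) - np.asarray(b)) % 360.0)
    return np.where(d > 180.0, 360.0 - d, d)


def wind_sector(point, road: RoadSource, wind: WindObservation,
                calm_threshold: float = 0.0) -> str:
    """Classify an observation as upwind or downwind of a road.

    A point is *downwind* iff the wind's blowing-toward bearing lies strictly
    within 90 degrees of the road-to-point bearing AND strictly more than 45
    degrees from the local road axis (either direction); everything else,
    including the exact sector boundaries, is *upwind* (conservative).  Calm
    winds (speed <= ``calm_threshold``, default exactly 0) return ``"calm"``
    and must be excluded from stratified fits.
    """
    res = wind_sector_array(
        np.asarray(point, float)[None, :], road,
        np.array([wind.speed]), np.array([wind.direction]),
        calm_threshold=calm_threshold,
    )
    return str(res[0])


def wind_sector_array(points, road: RoadSource, speeds, directions,
                      calm_threshold: float = 0.0) -> np.ndarray:
    """Vectorized :func:`wind_sector`; returns an object array of labels."""
    _check_road(road)
    pts = np.asarray(points, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    directions = np.asarray(directions, dtype=float) % 360.0
    s = np.asarray(_project(pts, road), dtype=float)
    near = road.point_at(s)
    v = pts - near
    on_road = np.linalg.norm(v, axis=1) < 1e-9
    bearing_rp = np.degrees(np.arctan2(v[:, 0], v[:, 1])) % 360.0
    axis = road.tangent_bearing_at(s)
    blow_toward = (directions + 180.0) % 360.0
    in_cone = _angdiff(blow_toward, bearing_rp) < 90.0
    off_axis = np.minimum(_angdiff(blow_toward, axis),
                          _angdiff(blow_toward, axis + 180.0)) > 45.0
    out = np.where(in_cone & off_axis & ~on_road, "downwind", "upwind").astype(object)
    out[speeds <= calm_threshold] = "calm"
    return out


# ---------------------------------------------------------------------------
# GeoJSON I/O — LineString features with {id, elevations, counter_ids}
# properties; coordinates are planar UTM meters (zone recorded file-level).

def read_roads_geojson(path) -> list:
    with open(path) as fh:
        gj = json.load(fh)
    roads = []
    for feat in gj.get("features", []):
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            raise ValueError(f"expected LineString features, got {geom['type']}")
        props = feat.get("properties", {})
        roads.append(RoadSource(
            id=props["id"],
            vertices=np.asarray(geom["coordinates"], dtype=float),
            elevation=np.asarray(props.get(
                "elevations", [0.0] * len(geom["coordinates"])), dtype=float),
            counter_ids=list(props.get("counter_ids", [])),
        ))
    return roads


def write_roads_geojson(roads, path, utm_zone: str = "18N") -> None:
    features = []
    for r in roads:
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[float(x), float(y)] for x, y in r.vertices]},
            "properties": {"id": r.id,
                           "elevations": [float(h) for h in r.elevation],
                           "counter_ids": list(r.counter_ids)},
        })
    gj = {"type": "FeatureCollection", "utm_zone": utm_zone, "features": features}
    with open(path, "w") as fh:
        json.dump(gj, fh, indent=1)
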