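"""Coastal/inland classification and per-group box-plot summaries.

A city is coastal when its representative point lies within ``buffer_km``
(10 km by default, boundary inclusive) of the coastline polyline, measured
as the great-circle distance to the nearest point of any segment (spherical
cross-track distance with endpoint clamping, R = 6371 km).  Coast groups
(West, South, East-North) come from the city table; inland cities get the
``Inland`` group.  Group summaries use Tukey box-plot statistics: median,
quartiles, whiskers at 1.5 x IQR beyond the box edges, and outliers beyond
the whiskers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import CityRecord, logger

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class CoastalClassification:
    city_id: str
    distance_km: float
    coastal: bool
    coast_group: str


@dataclass
class GroupBoxStats:
    """Tukey box-plot summary of one group's values."""

    group: str
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: list = field(default_factory=list)
    n: int = 0


# ---------------------------------------------------------------------------
# Great-circle geometry
# ---------------------------------------------------------------------------

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points, in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _bearing(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    y = math.sin(dl) * math.cos(p2)
    x = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    return math.atan2(y, x)


def point_segment_distance_km(lat: float, lon: float,
                              lat_a: float, lon_a: float,
                              lat_b: float, lon_b: float) -> float:
    """Great-circle distance from a point to the geodesic segment A-B.

    Cross-track distance when the along-track projection falls inside the
    segment, otherwise the distance to the nearer endpoint.
    """
    d_ab = haversine_km(lat_a, lon_a, lat_b, lon_b)
    d_ap = haversine_km(lat_a, lon_a, lat, lon)
    d_bp = haversine_km(lat_b, lon_b, lat, lon)
    if d_ab == 0.0:
        return d_ap
    theta_ab = _bearing(lat_a, lon_a, lat_b, lon_b)
    theta_ap = _bearing(lat_a, lon_a, lat, lon)
    delta_ap = d_ap / EARTH_RADIUS_KM
    dxt = math.asin(
        max(-1.0, min(1.0, math.sin(delta_ap) * math.sin(theta_ap - theta_ab))))
    # along-track arc length from A towards B
    cos_dxt = math.cos(dxt)
    if cos_dxt == 0.0:
        return min(d_ap, d_bp)
    dat = math.acos(max(-1.0, min(1.0, math.cos(delta_ap) / cos_dxt)))
    # projection outside the segment -> nearest endpoint
    if math.cos(theta_ap - theta_ab) < 0:  # behind A
        return d_ap
    if dat * EARTH_RADIUS_KM > d_ab:       # beyond B
        return d_bp
    return abs(dxt) * EARTH_RADIUS_KM


def load_coastline(source) -> list[np.ndarray]:
    """Extract polylines (arrays of [lon, lat]) from GeoJSON.

    Accepts a path, a GeoJSON string, or a parsed dict; handles LineString,
    MultiLineString, Feature and FeatureCollection wrappers.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        obj = json.loads(p.read_text() if p.exists() else str(source))
    else:
        obj = source
    lines: list[np.ndarray] = []

    def walk(geom):
        gtype = geom.get("type")
        if gtype == "LineString":
            lines.append(np.asarray(geom["coordinates"], dtype=float))
        elif gtype == "MultiLineString":
            for coords in geom["coordinates"]:
                lines.append(np.asarray(coords, dtype=float))
        elif gtype == "Feature":
            walk(geom["geometry"])
        elif gtype in ("FeatureCollection",):
            for f in geom["features"]:
                walk(f)
        elif gtype == "GeometryCollection":
            for g in geom["geometries"]:
                walk(g)
        else:
            raise ValueError(f"unsupported GeoJSON geometry {gtype!r}")

    walk(obj)
    lines = [ln for ln in lines if len(ln) >= 2]
    return lines


def distance_to_coastline_km(lat: float, lon: float,
                             coastline: Sequence[np.ndarray]) -> float:
    """Distance from a point to the nearest point of any coastline segment."""
    if not coastline:
        raise ValueError("empty coastline geometry")
    best = math.inf
    for line in coastline:
        for (lon_a, lat_a), (lon_b, lat_b) in zip(line[:-1], line[1:]):
            d = point_segment_distance_km(lat, lon, lat_a, lon_a, lat_b, lon_b)
            if d < best:
                best = d
    return best


def classify_coastal(city: CityRecord, coastline: Sequence[np.ndarray],
                     buffer_km: float = 10.0) -> CoastalClassification:
    """Classify one city against the coastline buffer (boundary inclusive)."""
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    dist = distance_to_coastline_km(city.lat, city.lon, coastline)
    coastal = dist <= buffer_km
    group = city.coast_group if coastal else "Inland"
    if coastal and group in ("Inland", "Unclassified"):
        logger.warning("city %s within %.1f km of coast but grouped %s",
                       city.city_id, dist, group)
    return CoastalClassification(city.city_id, dist, coastal, group)


# ---------------------------------------------------------------------------
# Box-plot statistics
# ---------------------------------------------------------------------------

def group_box_stats(values, group: str = "") -> GroupBoxStats:
    """Median, quartiles, 1.5 x IQR Tukey whiskers and outliers."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"empty group {group!r}")
    q25, med, q75 = np.percentile(vals, [25, 50, 75], method="linear")
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = sorted(vals[(vals < lo_fence) | (vals > hi_fence)].tolist())
    return GroupBoxStats(group, float(med), float(q25), float(q75),
                         float(inside.min()), float(inside.max()),
                         outliers, int(vals.size))


def summarize_groups(values_by_group: Mapping[str, Sequence[float]]
                     ) -> dict[str, GroupBoxStats]:
    return {g: group_box_stats(v, g) for g, v in values_by_group.items()}
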