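"""Geocoding, geodesic distance, pharmacy buffer zones, region aggregation.

Coordinates are WGS84 decimal degrees. Distances are great-circle
(haversine) with a fixed mean Earth radius of 3958.8 miles, so results are
deterministic and projection-free; at the 1/3-mile buffer scale the
discrepancy against projected planar buffers is negligible.

Geocoding is a pluggable backend; the shipped implementation is an offline
exact-match gazetteer (normalized address string -> point). Online services
can be plugged in but nothing here requires one.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_MILES",
    "MILES_PER_DEGREE",
    "GeoPoint",
    "BufferZone",
    "Gazetteer",
    "normalize_address",
    "geocode",
    "haversine_miles",
    "classify_against_buffers",
    "aggregate_by_region",
    "load_pharmacies",
    "buffers_to_geojson",
]

EARTH_RADIUS_MILES = 3958.8
#: miles per degree of latitude (2*pi*R/360)
MILES_PER_DEGREE = 2 * math.pi * EARTH_RADIUS_MILES / 360.0


@dataclass(frozen=True)
class GeoPoint:
    lat: float
    lng: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")
        if not -180.0 <= self.lng <= 180.0:
            raise ValueError(f"lng out of range: {self.lng}")


@dataclass(frozen=True)
class BufferZone:
    """Circular zone of `radius` miles around a resource point."""

    center: GeoPoint
    radius: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    def contains(self, point: GeoPoint) -> bool:
        return haversine_miles(self.center, point) <= self.radius


_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s]")


def normalize_address(address: str) -> str:
    """Casefold, strip punctuation, collapse whitespace.

    Applied identically when a gazetteer is built and when it is queried, so
    "  123  MAIN st." and "123 main st" resolve to the same key.
    """
    return _WS.sub(" ", _PUNCT.sub("", str(address).casefold())).strip()


class Gazetteer:
    """Deterministic offline geocoder: normalized address -> GeoPoint."""

    def __init__(self, mapping: dict[str, GeoPoint] | None = None):
        self._table: dict[str, GeoPoint] = {}
        for addr, point in (mapping or {}).items():
            self._table[normalize_address(addr)] = point

    def __len__(self) -> int:
        return len(self._table)

    def add(self, address: str, point: GeoPoint) -> None:
        self._table[normalize_address(address)] = point

    def lookup(self, address: str) -> GeoPoint | None:
        return self._table.get(normalize_address(address))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Gazetteer":
        """Load from a delimited table with columns address,lat,lng."""
        frame = pd.read_csv(path)
        gaz = cls()
        for _, row in frame.iterrows():
            gaz.add(str(row["address"]), GeoPoint(float(row["lat"]), float(row["lng"])))
        return gaz

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"address": addr, "lat": p.lat, "lng": p.lng}
            for addr, p in sorted(self._table.items())
        ]
        pd.DataFrame(rows, columns=["address", "lat", "lng"]).to_csv(path, index=False)


def geocode(address: str | None, gazetteer: Gazetteer) -> GeoPoint | None:
    """Exact lookup after normalization; None (logged) on a miss.

    Never raises on odd input — geocoding failures degrade to records
    without a spatial component.
    """
    if address is None or (isinstance(address, float) and pd.isna(address)):
        return None
    point = gazetteer.lookup(str(address))
    if point is None:
        logger.debug("gazetteer miss: %r", address)
    return point


def haversine_miles(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in miles on a sphere of radius 3958.8 mi."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlmb = math.radians(b.lng - a.lng)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_MILES * math.asin(min(1.0, math.sqrt(h)))


def classify_against_buffers(
    points: list[GeoPoint],
    resources: list[GeoPoint],
    radius: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Classify each point as inside/outside any resource buffer.

    A point is inside iff its distance to the nearest resource is <= radius.
    Returns a frame with columns lat, lng, nearest_miles, inside.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if not resources:
        raise ValueError("classification is undefined without resources")
    if not points:
        return pd.DataFrame(columns=["lat", "lng", "nearest_miles", "inside"])

    # vectorized all-pairs haversine
    plat = np.radians([p.lat for p in points])[:, None]
    plng = np.radians([p.lng for p in points])[:, None]
    rlat = np.radians([r.lat for r in resources])[None, :]
    rlng = np.radians([r.lng for r in resources])[None, :]
    h = (
        np.sin((rlat - plat) / 2) ** 2
        + np.cos(plat) * np.cos(rlat) * np.sin((rlng - plng) / 2) ** 2
    )
    dist = 2 * EARTH_RADIUS_MILES * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    nearest = dist.min(axis=1)
    return pd.DataFrame(
        {
            "lat": [p.lat for p in points],
            "lng": [p.lng for p in points],
            "nearest_miles": nearest,
            "inside": nearest <= radius,
        }
    )


def _region_lookup(region_polygons: str | Path | dict) -> list[tuple[str, object]]:
    """Load a GeoJSON feature collection into (region_id, shapely geometry)."""
    if not isinstance(region_polygons, dict):
        region_polygons = json.loads(Path(region_polygons).read_text(encoding="utf-8"))
    out = []
    for feature in region_polygons.get("features", []):
        props = feature.get("properties", {})
        region_id = props.get("region_id") or props.get("id") or props.get("name")
        if region_id is None:
            raise ValueError("region feature lacks a region_id property")
        out.append((str(region_id), shape(feature["geometry"])))
    return out


def aggregate_by_region(
    records: pd.DataFrame,
    level: str,
    region_polygons: str | Path | dict | None = None,
) -> tuple[dict[str, int], int]:
    """Count records per region at zip or county level.

    A record contributes through its own zip/county column when populated;
    otherwise, a point-resolution record is assigned by point-in-polygon
    against supplied region polygons. Records at a coarser resolution than
    the requested level are never upscaled: they land in the unaggregable
    bucket. Counts conserve: sum(counts) + unaggregable == len(records).
    """
    if level not in {"zip", "county"}:
        raise ValueError(f"level must be 'zip' or 'county', got {level!r}")
    column = {"zip": "injury_zip", "county": "county"}[level]
    fallback = {"zip": "residence_zip", "county": None}[level]
    regions = _region_lookup(region_polygons) if region_polygons is not None else []

    counts: dict[str, int] = {}
    unaggregable = 0
    for _, row in records.iterrows():
        value = row.get(column)
        if (pd.isna(value) or str(value).strip() == "") and fallback:
            value = row.get(fallback)
        if pd.notna(value) and str(value).strip():
            key = str(value).strip()
            counts[key] = counts.get(key, 0) + 1
            continue
        lat, lng = row.get("lat"), row.get("lng")
        if regions and pd.notna(lat) and pd.notna(lng):
            point = Point(float(lng), float(lat))
            for region_id, geom in regions:
                if geom.covers(point):
                    counts[region_id] = counts.get(region_id, 0) + 1
                    break
            else:
                unaggregable += 1
            continue
        unaggregable += 1
    return counts, unaggregable


def load_pharmacies(path: str | Path) -> list[GeoPoint]:
    """Read a pharmacy point file (delimited: id,name,lat,lng)."""
    frame = pd.read_csv(path)
    return [GeoPoint(float(r["lat"]), float(r["lng"])) for _, r in frame.iterrows()]


def _circle_coords(zone: BufferZone, n_vertices: int = 64) -> list[list[float]]:
    """Discretize a buffer circle in lng/lat using local degree scaling."""
    dlat = zone.radius / MILES_PER_DEGREE
    dlng = zone.radius / (MILES_PER_DEGREE * math.cos(math.radians(zone.center.lat)))
    coords = []
    for k in range(n_vertices + 1):
        theta = 2 * math.pi * k / n_vertices
        coords.append(
            [
                zone.center.lng + dlng * math.cos(theta),
                zone.center.lat + dlat * math.sin(theta),
            ]
        )
    return coords


def buffers_to_geojson(
    zones: list[BufferZone],
    points: pd.DataFrame | None = None,
    n_vertices: int = 64,
) -> dict:
    """GeoJSON export: buffer circles (64-vertex polygons) plus classified points."""
    features = [
        {
            "type": "Feature",
            "properties": {"kind": "buffer", "radius_miles": z.radius},
            "geometry": {"type": "Polygon", "coordinates": [_circle_coords(z, n_vertices)]},
        }
        for z in zones
    ]
    if points is not None:
        for _, row in points.iterrows():
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "kind": "event",
                        "inside": bool(row["inside"]),
                        "nearest_miles": float(row["nearest_miles"]),
                    },
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(row["lng"]), float(row["lat"])],
                    },
                }
            )
    return {"type": "FeatureCollection", "features": features}
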