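"""Geodesy helpers and GeoJSON I/O for geospatial unit polygons.

Units are stored as a plain ``pandas.DataFrame`` with a ``unit_id`` column and
a ``geometry`` column of shapely polygons in WGS84 lon/lat.  Distances are
great-circle (haversine) on a sphere of radius 6 371 000 m; a locally
projected Euclidean alternative is provided for comparison at city scales,
where the two agree to well under a metre over tens of metres.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_m",
    "equirectangular_m",
    "offset_lonlat",
    "write_units_geojson",
    "read_units_geojson",
    "validate_disjoint_units",
]


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between lon/lat points (degrees).

    Accepts scalars or numpy arrays; symmetric; zero iff the points coincide.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    if np.isscalar(lon1) or d.ndim == 0:
        return float(d)
    return d


def equirectangular_m(lon1, lat1, lon2, lat2):
    """Planar Euclidean distance after an equirectangular projection.

    Projects about the mean latitude of the two points; adequate over the
    sub-kilometre scales where stay detection operates.
    """
    lat0 = math.radians((np.mean(lat1) + np.mean(lat2)) / 2.0)
    kx = math.cos(lat0) * math.pi / 180.0 * EARTH_RADIUS_M
    ky = math.pi / 180.0 * EARTH_RADIUS_M
    dx = (np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float)) * kx
    dy = (np.asarray(lat2, dtype=float) - np.asarray(lat1, dtype=float)) * ky
    d = np.hypot(dx, dy)
    return float(d) if d.ndim == 0 else d


def offset_lonlat(lon: float, lat: float, dx_m: float, dy_m: float) -> tuple[float, float]:
    """Displace a lon/lat point by metric offsets (east ``dx_m``, north ``dy_m``)."""
    dlat = dy_m / EARTH_RADIUS_M * 180.0 / math.pi
    dlon = dx_m / (EARTH_RADIUS_M * math.cos(math.radians(lat))) * 180.0 / math.pi
    return lon + dlon, lat + dlat


def write_units_geojson(units: pd.DataFrame, path) -> None:
    """Write units as a GeoJSON FeatureCollection with an ``unit_id`` property.

    Extra columns of ``units`` become feature properties.  Output key order is
    fixed so identical inputs yield byte-identical files.
    """
    features = []
    prop_cols = [c for c in units.columns if c != "geometry"]
    for _, row in units.iterrows():
        features.append(
            {
                "type": "Feature",
                "properties": {c: row[c] for c in prop_cols},
                "geometry": mapping(row["geometry"]),
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_units_geojson(path) -> pd.DataFrame:
    """Read a FeatureCollection of unit polygons into a units DataFrame."""
    with open(path) as fh:
        payload = json.load(fh)
    rows = []
    for feat in payload["features"]:
        props = dict(feat.get("properties") or {})
        if "unit_id" not in props:
            raise ValueError("unit feature without an 'unit_id' property")
        props["geometry"] = shape(feat["geometry"])
        rows.append(props)
    units = pd.DataFrame(rows)
    if units["unit_id"].duplicated().any():
        raise ValueError("duplicate unit_id in units file")
    return units


def validate_disjoint_units(units: pd.DataFrame) -> None:
    """Raise ``ValueError`` if any two unit polygons have overlapping interiors.

    Shared boundaries (edge-adjacent grid cells) are allowed.
    """
    geoms = list(units["geometry"])
    ids = list(units["unit_id"])
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if not inter.is_empty and inter.area > 0:
                raise ValueError(
                    f"units {ids[i]!r} and {ids[j]!r} have overlapping interiors"
                )
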