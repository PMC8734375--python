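"""Practice geolocation and region assignment.

Practices are geocoded by joining their normalised postcode against an
NSPL-style lookup (postcode → WGS84 lon/lat) and assigned to regions by
point-in-polygon containment against published boundary polygons.

Containment is even-odd ray casting on planar lon/lat coordinates — at the
scale of English commissioning regions the geodesic correction is negligible
(documented limitation).  Points lying exactly on a boundary edge count as
inside (closed polygons), a deterministic tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import normalise_postcode

GEO_COLUMNS = ["practice", "name", "address", "postcode", "lon", "lat", "region"]

Ring = list[tuple[float, float]]


@dataclass
class RegionBoundary:
    """Named region polygon(s): each polygon is [outer ring, *hole rings].

    Rings are closed (first point repeated last) ordered (lon, lat) pairs;
    even-odd containment makes ring orientation irrelevant in practice.
    """

    name: str
    polygons: list[list[Ring]]

    def __post_init__(self) -> None:
        for poly in self.polygons:
            for ring in poly:
                if len(ring) < 4:
                    raise ValueError(f"region {self.name!r}: ring with {len(ring)} points (< 4)")
                if tuple(ring[0]) != tuple(ring[-1]):
                    raise ValueError(f"region {self.name!r}: ring not closed")


def read_boundaries(path: str | Path, name_property: str = "name") -> list[RegionBoundary]:
    """Read a GeoJSON-style FeatureCollection of Polygon/MultiPolygon features."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    out = []
    for feature in gj.get("features", []):
        name = str(feature.get("properties", {}).get(name_property, ""))
        geom = feature.get("geometry", {})
        gtype = geom.get("type")
        coords = geom.get("coordinates", [])
        if gtype == "Polygon":
            polys = [coords]
        elif gtype == "MultiPolygon":
            polys = coords
        else:
            raise ValueError(f"unsupported geometry type {gtype!r} for region {name!r}")
        out.append(
            RegionBoundary(
                name=name,
                polygons=[[[(float(x), float(y)) for x, y in ring] for ring in poly] for poly in polys],
            )
        )
    return out


def geolocate_practices(directory: pd.DataFrame, lookup: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join the practice directory to the postcode lookup → (geo table, log).

    Postcodes are normalised on both sides before joining.  Practices whose
    postcode is absent from the lookup are retained with missing coordinates
    and listed in the log — never dropped.
    """
    d = directory.copy()
    d["postcode"] = d["postcode"].map(normalise_postcode)
    lk = lookup.copy()
    lk["postcode"] = lk["postcode"].map(normalise_postcode)
    lk = lk.drop_duplicates(subset=["postcode"])
    merged = d.merge(lk[["postcode", "lon", "lat"]], on="postcode", how="left")
    merged["region"] = None
    unmatched = merged[merged["lon"].isna()][["practice", "postcode"]].copy()
    unmatched["reason"] = "postcode not in lookup"
    for col in GEO_COLUMNS:
        if col not in merged.columns:
            merged[col] = None
    return merged[GEO_COLUMNS], unmatched.reset_index(drop=True)


def _on_segment(px: float, py: float, ax: float, ay: float, bx: float, by: float) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > 1e-12:
        return False
    return min(ax, bx) - 1e-12 <= px <= max(ax, bx) + 1e-12 and \
        min(ay, by) - 1e-12 <= py <= max(ay, by) + 1e-12


def _ring_crossings(px: float, py: float, ring: Ring) -> tuple[int, bool]:
    """(number of upward/downward edge crossings of the +x ray, on-boundary)."""
    inside_count = 0
    on_edge = False
    for (ax, ay), (bx, by) in zip(ring[:-1], ring[1:]):
        if _on_segment(px, py, ax, ay, bx, by):
            on_edge = True
        if (ay > py) != (by > py):
            x_at = ax + (py - ay) * (bx - ax) / (by - ay)
            if x_at > px:
                inside_count += 1
    return inside_count, on_edge


def point_in_region(lon: float, lat: float, boundary: RegionBoundary) -> bool:
    """Even-odd containment of (lon, lat); boundary points count as inside."""
    for poly in boundary.polygons:
        crossings = 0
        for ring in poly:
            c, on_edge = _ring_crossings(lon, lat, ring)
            if on_edge:
                return True
            crossings += c
        if crossings % 2 == 1:
            return True
    return False


def practices_in_region(geo_table: pd.DataFrame, boundary: RegionBoundary) -> list[str]:
    """Practice codes with coordinates strictly resolved inside *boundary*, sorted."""
    out = []
    for _, row in geo_table.iterrows():
        lon, lat = row.get("lon"), row.get("lat")
        if lon is None or lat is None or pd.isna(lon) or pd.isna(lat):
            continue
        if point_in_region(float(lon), float(lat), boundary):
            out.append(str(row["practice"]))
    return sorted(out)


def assign_regions(geo_table: pd.DataFrame, boundaries: list[RegionBoundary]) -> pd.DataFrame:
    """Fill the region column with the first boundary containing each point."""
    out = geo_table.copy()
    regions = []
    for _, row in out.iterrows():
        lon, lat = row.get("lon"), row.get("lat")
        region = None
        if lon is not None and lat is not None and not pd.isna(lon) and not pd.isna(lat):
            for b in boundaries:
                if point_in_region(float(lon), float(lat), b):
                    region = b.name
                    break
        regions.append(region)
    out["region"] = regions
    return out
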