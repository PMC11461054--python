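"""Hotspot region polygons and point-in-region assignment.

Regions are read from a GeoJSON FeatureCollection whose features carry a
``name`` property. The package ships approximate boundaries for the five
named hotspots (Med, NOR, NB, WEB, Canaries); any position outside all of
them is labelled ``Migratory``. Overlaps are resolved by a fixed precedence
order (Med > NOR > NB > WEB > Canaries), so assignment is a partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import shapely
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "HotspotRegion",
    "PRECEDENCE",
    "MIGRATORY",
    "load_regions",
    "assign_hotspot",
    "assign_hotspots",
]

PRECEDENCE = ("Med", "NOR", "NB", "WEB", "Canaries")
MIGRATORY = "Migratory"


@dataclass(frozen=True)
class HotspotRegion:
    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"region {self.name!r} has an invalid geometry")


def load_regions(path: str | None = None) -> list[HotspotRegion]:
    """Load hotspot polygons from GeoJSON; packaged boundaries by default.

    Regions are returned in precedence order; unknown names are kept after
    the known ones, in file order.
    """
    if path is None:
        text = (
            resources.files("psatkit").joinpath("data/hotspots.geojson").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    gj = json.loads(text)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("regions file must be a GeoJSON FeatureCollection")
    regs = []
    for feat in gj["features"]:
        name = feat.get("properties", {}).get("name")
        if not name:
            raise ValueError("every region feature needs a 'name' property")
        regs.append(HotspotRegion(name=str(name), geometry=shape(feat["geometry"])))
    order = {n: i for i, n in enumerate(PRECEDENCE)}
    regs.sort(key=lambda r: order.get(r.name, len(order)))
    return regs


def assign_hotspot(
    lon: float, lat: float, regions: list[HotspotRegion]
) -> str:
    """Label one position: first containing region in precedence order,
    else ``Migratory``. Boundary points count as inside."""
    if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
        raise ValueError(f"invalid coordinates ({lon}, {lat})")
    pt = shapely.points(lon, lat)
    for reg in regions:
        if reg.geometry.intersects(pt):
            return reg.name
    return MIGRATORY


def assign_hotspots(
    lons: np.ndarray, lats: np.ndarray, regions: list[HotspotRegion]
) -> np.ndarray:
    """Vectorized region assignment for arrays of positions."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if np.any(np.abs(lats) > 90.0) or np.any(np.abs(lons) > 180.0):
        raise ValueError("coordinates outside valid lon/lat ranges")
    labels = np.full(lons.shape, MIGRATORY, dtype=object)
    unassigned = np.ones(lons.shape, dtype=bool)
    for reg in regions:
        if not unassigned.any():
            break
        prepped = shapely.prepare(reg.geometry)
        hit = unassigned & shapely.intersects_xy(reg.geometry, lons, lats)
        labels[hit] = reg.name
        unassigned &= ~hit
    return labels.astype(str)
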