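"""Coverage mapping: class areas in square meters, vector polygons, zone
reports, and GeoJSON export.

Areas follow the pixel-count identity: with a ground sample distance g (m per
pixel) a class covering n pixels occupies exactly n * g^2 square meters.
Polygons are traced along pixel boundaries (staircase outlines, holes
preserved), so the sum of polygon areas over all connected components equals
the pixel-count area exactly — no smoothing is applied by default because it
would break that identity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box, mapping as shp_mapping, shape as shp_shape
from shapely.ops import unary_union

from .raster_io import (CLASS_NAMES, GeoRaster, GeoRef, UngeoreferencedError)

__all__ = ["CoveragePolygon", "CoverageReport", "class_area", "polygonize",
           "zone_report", "export_geojson", "import_geojson",
           "export_coverage_raster"]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class CoveragePolygon:
    """One connected patch of a class, vectorized in CRS coordinates.

    ``geometry`` is a shapely Polygon (or MultiPolygon when pixels of an
    8-connected component touch only at corners). ``area_m2`` is defined by
    the pixel-count identity pixel_count * gsd^2.
    """

    geometry: Union[Polygon, MultiPolygon]
    class_name: str
    pixel_count: int
    area_m2: float


@dataclass
class CoverageReport:
    """Per-class scene totals and per-zone areas, all in square meters."""

    scene_id: str
    gsd: float
    class_areas_m2: Dict[str, float]
    zone_areas_m2: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: Optional[str] = None) -> str:
        payload = {
            "scene_id": self.scene_id,
            "gsd_m_per_pixel": self.gsd,
            "class_areas_m2": dict(sorted(self.class_areas_m2.items())),
            "zone_areas_m2": {z: dict(sorted(a.items()))
                              for z, a in sorted(self.zone_areas_m2.items())},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _class_index(cls: Union[int, str], names: Sequence[str]) -> int:
    if isinstance(cls, str):
        try:
            return names.index(cls)
        except ValueError:
            raise KeyError(f"unknown class name {cls!r}; known: {tuple(names)}")
    return int(cls)


def class_area(mask: GeoRaster, cls: Union[int, str],
               class_names: Sequence[str] = CLASS_NAMES) -> float:
    """Area of one class in square meters: (#pixels) * gsd^2."""
    georef = mask.require_georef()
    if not mask.is_mask:
        raise ValueError("class_area expects a label mask raster")
    idx = _class_index(cls, class_names)
    n = int((mask.data == idx).sum())
    return n * georef.gsd ** 2


def _component_geometry(rows: np.ndarray, cols: np.ndarray,
                        georef: GeoRef) -> Union[Polygon, MultiPolygon]:
    """Union of pixel squares for one component, in CRS coordinates.

    Pixels are merged into horizontal runs first to keep the union cheap.
    """
    g = georef.gsd
    ox, oy = georef.origin
    boxes = []
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    i = 0
    n = len(rows)
    while i < n:
        r, c0 = rows[i], cols[i]
        j = i
        while j + 1 < n and rows[j + 1] == r and cols[j + 1] == cols[j] + 1:
            j += 1
        c1 = cols[j]
        boxes.append(box(ox + c0 * g, oy - (r + 1) * g,
                         ox + (c1 + 1) * g, oy - r * g))
        i = j + 1
    geom = unary_union(boxes)
    return geom


def polygonize(mask: GeoRaster, cls: Union[int, str], connectivity: int = 8,
               min_area_m2: float = 0.0,
               class_names: Sequence[str] = CLASS_NAMES
               ) -> List[CoveragePolygon]:
    """Vectorize the connected components of one class into polygons.

    Components are found with 8-connectivity by default (sargassum windrows
    run diagonally along the wrack line); each becomes one CoveragePolygon
    whose geometry follows pixel boundaries exactly. Components smaller than
    ``min_area_m2`` are dropped; with the default 0 the polygon areas sum to
    ``class_area`` exactly.
    """
    georef = mask.require_georef()
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    idx = _class_index(cls, class_names)
    name = class_names[idx] if idx < len(class_names) else str(idx)
    binary = mask.data == idx
    labeled, n_comp = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    out: List[CoveragePolygon] = []
    if n_comp == 0:
        return out
    comp_slices = ndimage.find_objects(labeled)
    for comp, sl in enumerate(comp_slices, start=1):
        sub = labeled[sl] == comp
        rr, cc = np.nonzero(sub)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        count = len(rows)
        area = count * georef.gsd ** 2
        if area < min_area_m2:
            continue
        out.append(CoveragePolygon(
            geometry=_component_geometry(rows, cols, georef),
            class_name=name, pixel_count=count, area_m2=area))
    return out


def zone_report(mask: GeoRaster, zones: Dict[str, Tuple[float, float, float, float]],
                scene_id: str = "",
                class_names: Sequence[str] = CLASS_NAMES) -> CoverageReport:
    """Per-zone, per-class areas by pixel-center membership.

    Zones are named CRS rectangles ``(xmin, ymin, xmax, ymax)`` with half-open
    membership ``[min, max)`` on both axes, so rectangles that tile the scene
    partition its pixels exactly. A zone that misses the scene footprint is
    reported with zero areas and a warning.
    """
    georef = mask.require_georef()
    if not mask.is_mask:
        raise ValueError("zone_report expects a label mask raster")
    h, w = mask.data.shape
    xs, _ = georef.pixel_center(0, np.arange(w))
    _, ys = georef.pixel_center(np.arange(h), 0)
    n_classes = max(len(class_names), int(mask.data.max()) + 1)
    totals = np.bincount(mask.data.ravel(), minlength=n_classes)
    g2 = georef.gsd ** 2
    class_areas = {class_names[k]: float(totals[k] * g2)
                   for k in range(len(class_names))}
    zone_areas: Dict[str, Dict[str, float]] = {}
    for zname, (xmin, ymin, xmax, ymax) in zones.items():
        in_x = (xs >= xmin) & (xs < xmax)
        in_y = (ys >= ymin) & (ys < ymax)
        if not in_x.any() or not in_y.any():
            warnings.warn(f"zone {zname!r} does not intersect the scene footprint")
            zone_areas[zname] = {n: 0.0 for n in class_names}
            continue
        sub = mask.data[np.ix_(in_y, in_x)]
        counts = np.bincount(sub.ravel(), minlength=n_classes)
        zone_areas[zname] = {class_names[k]: float(counts[k] * g2)
                             for k in range(len(class_names))}
    return CoverageReport(scene_id=scene_id, gsd=georef.gsd,
                          class_areas_m2=class_areas, zone_areas_m2=zone_areas)


def export_geojson(polygons: Sequence[CoveragePolygon], path: str,
                   crs: Optional[str] = None) -> None:
    """Write polygons as an RFC 7946 FeatureCollection with area properties."""
    features = []
    for poly in polygons:
        features.append({
            "type": "Feature",
            "geometry": shp_mapping(poly.geometry),
            "properties": {
                "class": poly.class_name,
                "area_m2": poly.area_m2,
                "pixel_count": poly.pixel_count,
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    if crs:
        collection["crs_note"] = crs
    with open(path, "w") as fh:
        json.dump(collection, fh)


def import_geojson(path: str) -> List[CoveragePolygon]:
    """Re-read an exported FeatureCollection (round-trip counterpart)."""
    with open(path) as fh:
        collection = json.load(fh)
    out = []
    for feat in collection.get("features", []):
        props = feat.get("properties", {})
        out.append(CoveragePolygon(
            geometry=shp_shape(feat["geometry"]),
            class_name=props.get("class", ""),
            pixel_count=int(props.get("pixel_count", 0)),
            area_m2=float(props.get("area_m2", 0.0))))
    return out


def export_coverage_raster(mask: GeoRaster, path: str) -> None:
    """Write the class mask as a georeferenced single-band raster."""
    from .raster_io import write_raster
    if not mask.is_mask:
        raise ValueError("expected a label mask raster")
    write_raster(mask, path)
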