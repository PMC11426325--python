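import json

import numpy as np
import pytest

from sargmap.mapping import (class_area, export_geojson, import_geojson,
                             polygonize, zone_report)
from sargmap.raster_io import GeoRaster, GeoRef, UngeoreferencedError


def georaster(mask, gsd=0.02, origin=None, crs="LOCAL:metric"):
    mask = np.asarray(mask, dtype=np.uint8)
    origin = origin or (0.0, mask.shape[0] * gsd)
    return GeoRaster(mask, GeoRef(gsd=gsd, origin=origin, crs=crs))


def shoelace(ring):
    xy = np.asarray(ring)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def geometry_area_from_coords(geom_mapping):
    """Re-derive the polygon area from raw GeoJSON rings (holes subtract)."""
    gtype = geom_mapping["type"]
    polys = ([geom_mapping["coordinates"]] if gtype == "Polygon"
             else geom_mapping["coordinates"])
    total = 0.0
    for rings in polys:
        total += shoelace(rings[0]) - sum(shoelace(r) for r in rings[1:])
    return total


class TestClassArea:
    def test_single_pixel_at_2cm(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[1, 2] = 2
        assert class_area(georaster(mask), "sargassum") \
            == pytest.approx(0.0004)

    def test_large_count_gives_123_m2(self):
        # 307,500 pixels at 2 cm GSD cover exactly 123 m^2
        mask = np.zeros((500, 800), np.uint8)
        mask.ravel()[:307500] = 2
        assert class_area(georaster(mask), "sargassum") == pytest.approx(123.0)

    def test_zero_pixels_zero_area(self):
        assert class_area(georaster(np.zeros((4, 4))), 2) == 0.0

    def test_ungeoreferenced_fails_loudly(self):
        with pytest.raises(UngeoreferencedError):
            class_area(GeoRaster(np.zeros((4, 4), np.uint8)), 2)

    def test_doubling_gsd_quadruples_area(self, rng):
        mask = rng.integers(0, 3, (32, 32)).astype(np.uint8)
        a1 = class_area(georaster(mask, gsd=0.02), 2)
        a2 = class_area(georaster(mask, gsd=0.04), 2)
        assert a2 == pytest.approx(4 * a1)


class TestPolygonize:
    def test_single_pixel_square(self):
        mask = np.zeros((3, 3), np.uint8)
        mask[1, 1] = 2
        (poly,) = polygonize(georaster(mask), "sargassum")
        assert poly.pixel_count == 1
        assert poly.area_m2 == pytest.approx(0.0004)
        assert poly.geometry.area == pytest.approx(0.0004, rel=1e-9)

    def test_2x2_block_single_polygon(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[1:3, 1:3] = 2
        polys = polygonize(georaster(mask), 2)
        assert len(polys) == 1
        assert polys[0].area_m2 == pytest.approx(4 * 0.0004)

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[0, 0] = mask[1, 1] = 2
        assert len(polygonize(georaster(mask), 2, connectivity=8)) == 1
        assert len(polygonize(georaster(mask), 2, connectivity=4)) == 2

    def test_area_conservation_random_mask(self, rng):
        mask = (rng.random((48, 64)) < 0.3).astype(np.uint8) * 2
        raster = georaster(mask)
        polys = polygonize(raster, 2)
        # conservation is exact in the integer pixel-count domain ...
        assert sum(p.pixel_count for p in polys) == int((mask == 2).sum())
        # ... and holds to the last few ulps once scaled by gsd^2
        assert sum(p.area_m2 for p in polys) \
            == pytest.approx(class_area(raster, 2), rel=1e-12)
        geo = sum(p.geometry.area for p in polys)
        assert geo == pytest.approx(class_area(raster, 2), rel=1e-9)

    def test_min_area_filter(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[0, 0] = 2            # 0.0004 m^2
        mask[4:8, 4:8] = 2        # 0.0064 m^2
        polys = polygonize(georaster(mask), 2, min_area_m2=0.001)
        assert len(polys) == 1 and polys[0].pixel_count == 16

    def test_hole_preserved(self):
        mask = np.full((5, 5), 2, np.uint8)
        mask[2, 2] = 0
        (poly,) = polygonize(georaster(mask), 2)
        assert poly.pixel_count == 24
        assert poly.geometry.area == pytest.approx(24 * 0.0004, rel=1e-9)
        assert len(poly.geometry.interiors) == 1

    def test_translation_changes_coords_not_area(self, rng):
        mask = (rng.random((16, 16)) < 0.4).astype(np.uint8) * 2
        a = polygonize(georaster(mask, origin=(0, 10)), 2)
        b = polygonize(georaster(mask, origin=(500, 900)), 2)
        assert sum(p.geometry.area for p in a) \
            == pytest.approx(sum(p.geometry.area for p in b), rel=1e-12)
        assert a[0].geometry.bounds != b[0].geometry.bounds


class TestZoneReport:
    def test_whole_scene_zone_equals_class_area(self, rng):
        mask = rng.integers(0, 3, (20, 30)).astype(np.uint8)
        raster = georaster(mask)
        g = raster.georef
        zone = (g.origin[0], g.origin[1] - 20 * g.gsd,
                g.origin[0] + 30 * g.gsd, g.origin[1])
        rep = zone_report(raster, {"all": zone})
        assert rep.zone_areas_m2["all"]["sargassum"] \
            == class_area(raster, "sargassum")

    def test_tiling_zones_partition_area(self, rng):
        mask = rng.integers(0, 3, (20, 30)).astype(np.uint8)
        raster = georaster(mask)
        g = raster.georef
        xmid = g.origin[0] + 15 * g.gsd
        top = g.origin[1]
        bot = top - 20 * g.gsd
        rep = zone_report(raster, {
            "west": (g.origin[0], bot, xmid, top),
            "east": (xmid, bot, g.origin[0] + 30 * g.gsd, top),
        })
        for cls in ("other", "sand", "sargassum"):
            assert rep.zone_areas_m2["west"][cls] + rep.zone_areas_m2["east"][cls] \
                == pytest.approx(rep.class_areas_m2[cls])

    def test_half_open_edge_pixel_in_exactly_one_zone(self):
        # a 2x1 mask whose two pixel centers straddle x = 0.02; the shared
        # boundary x=0.01 lies on no center, but make zones split exactly on
        # a center to check [min, max) semantics
        mask = np.array([[2, 2]], np.uint8)
        raster = georaster(mask, gsd=0.02, origin=(0.0, 0.02))
        # centers at x = 0.01 and 0.03; boundary exactly on the first center,
        # which the half-open convention pushes entirely into the right zone
        # (the left zone then holds no centers at all and warns)
        with pytest.warns(UserWarning, match="left"):
            rep = zone_report(raster, {
                "left": (-1.0, -1.0, 0.01, 1.0),
                "right": (0.01, -1.0, 1.0, 1.0),
            })
        total = rep.zone_areas_m2["left"]["sargassum"] \
            + rep.zone_areas_m2["right"]["sargassum"]
        assert total == pytest.approx(class_area(raster, 2))
        assert rep.zone_areas_m2["right"]["sargassum"] \
            == pytest.approx(class_area(raster, 2))

    def test_disjoint_zone_warns_and_reports_zero(self, rng):
        raster = georaster(rng.integers(0, 3, (4, 4)).astype(np.uint8))
        with pytest.warns(UserWarning, match="far"):
            rep = zone_report(raster, {"far": (100, 100, 101, 101)})
        assert rep.zone_areas_m2["far"]["sargassum"] == 0.0


class TestGeoJson:
    def test_roundtrip_preserves_features_and_areas(self, tmp_path, rng):
        mask = (rng.random((24, 24)) < 0.25).astype(np.uint8) * 2
        polys = polygonize(georaster(mask), 2)
        path = str(tmp_path / "cover.geojson")
        export_geojson(polys, path, crs="LOCAL:metric")
        back = import_geojson(path)
        assert len(back) == len(polys)
        for a, b in zip(polys, back):
            assert b.area_m2 == pytest.approx(a.area_m2, rel=1e-9)
            assert b.geometry.equals(a.geometry)

    def test_empty_collection_valid(self, tmp_path):
        path = str(tmp_path / "empty.geojson")
        export_geojson([], path)
        with open(path) as fh:
            doc = json.load(fh)
        assert doc == {"type": "FeatureCollection", "features": []}

    def test_shoelace_recheck_from_raw_coordinates(self, tmp_path, rng):
        mask = (rng.random((32, 32)) < 0.3).astype(np.uint8) * 2
        polys = polygonize(georaster(mask), 2)
        path = str(tmp_path / "cover.geojson")
        export_geojson(polys, path)
        with open(path) as fh:
            doc = json.load(fh)
        for feat in doc["features"]:
            area = geometry_area_from_coords(feat["geometry"])
            assert area == pytest.approx(feat["properties"]["area_m2"],
                                         rel=1e-6)
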