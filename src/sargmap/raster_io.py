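"""Raster and label-mask I/O with georeferencing.

Images are plain numpy arrays: an RGB image is ``(H, W, 3) uint8``, a label
mask is ``(H, W) uint8`` with class indices ``0=other, 1=sand, 2=sargassum``.
A :class:`ClassPalette` maps class indices to display colors; palette-encoded
masks are the interchange format between the generator output (continuous RGB)
and everything downstream (metrics, mapping).

Georeferencing is carried by :class:`GeoRef` (square pixels, ground sample
distance in meters per pixel, top-left corner origin in CRS coordinates,
northing decreasing with row index). Supported containers: GeoTIFF (pixel
scale / tiepoint tags), PNG with an ESRI world-file sidecar, or bare PNG for
ungeoreferenced tiles.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from PIL import Image
import tifffile

__all__ = [
    "CLASS_OTHER",
    "CLASS_SAND",
    "CLASS_SARGASSUM",
    "CLASS_NAMES",
    "ClassPalette",
    "DEFAULT_PALETTE",
    "GeoRef",
    "GeoRaster",
    "UngeoreferencedError",
    "encode_mask",
    "decode_mask",
    "read_raster",
    "write_raster",
]

CLASS_OTHER = 0
CLASS_SAND = 1
CLASS_SARGASSUM = 2
CLASS_NAMES = ("other", "sand", "sargassum")

# GeoTIFF tags (subset sufficient for a local metric grid with square pixels)
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


class UngeoreferencedError(ValueError):
    """Raised when an operation requiring georeferencing gets a bare raster."""


@dataclass(frozen=True)
class ClassPalette:
    """Ordered mapping of class names to RGB display colors.

    The index order is fixed package-wide as [other, sand, sargassum]; colors
    must be pairwise distinct so nearest-color decoding is well defined.
    """

    names: tuple = CLASS_NAMES
    colors: tuple = ((0, 255, 255), (255, 255, 0), (255, 0, 0))

    def __post_init__(self):
        if len(self.names) != len(self.colors):
            raise ValueError("palette names and colors must have equal length")
        if len({tuple(c) for c in self.colors}) != len(self.colors):
            raise ValueError("palette colors must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def color_array(self) -> np.ndarray:
        return np.asarray(self.colors, dtype=np.uint8)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown class name {name!r}; known: {self.names}")

    def min_color_distance(self) -> float:
        """Smallest pairwise Euclidean distance between palette colors."""
        c = self.color_array.astype(np.float64)
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        d[np.diag_indices(len(self))] = np.inf
        return float(d.min())

    @classmethod
    def from_mapping(cls, mapping) -> "ClassPalette":
        """Build from an ordered ``{name: [R, G, B]}`` mapping (config file)."""
        names = tuple(mapping.keys())
        colors = tuple(tuple(int(v) for v in rgb) for rgb in mapping.values())
        return cls(names=names, colors=colors)


DEFAULT_PALETTE = ClassPalette()


@dataclass(frozen=True)
class GeoRef:
    """Georeference of a raster: square pixels, top-left corner origin.

    ``gsd`` is the ground sample distance in meters per pixel; ``origin`` is
    the (easting, northing) of the top-left *corner* of pixel (0, 0); northing
    decreases with increasing row index.
    """

    gsd: float
    origin: tuple = (0.0, 0.0)
    crs: Optional[str] = None

    def __post_init__(self):
        if not (self.gsd > 0):
            raise ValueError(f"gsd must be positive, got {self.gsd}")

    def pixel_center(self, row, col):
        """CRS coordinates of pixel centers (vectorized over row/col)."""
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.gsd
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.gsd
        return x, y


@dataclass
class GeoRaster:
    """An RGB image or label mask, optionally georeferenced.

    ``data`` is ``(H, W, 3) uint8`` for images or ``(H, W) uint8`` for masks.
    """

    data: np.ndarray
    georef: Optional[GeoRef] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3) or self.data.size == 0:
            raise ValueError("raster data must be a non-empty 2-D or 3-D array")
        if self.data.ndim == 3 and self.data.shape[2] != 3:
            raise ValueError("3-D raster data must have 3 channels")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def is_mask(self) -> bool:
        return self.data.ndim == 2

    def require_georef(self) -> GeoRef:
        if self.georef is None:
            raise UngeoreferencedError(
                "ungeoreferenced raster: this operation needs a GSD/origin "
                "(read a GeoTIFF or provide a world file)"
            )
        return self.georef


def _validate_mask(mask: np.ndarray, n_classes: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if mask.size and mask.max() >= n_classes:
        bad = int(mask.max())
        raise ValueError(
            f"label {bad} out of palette range (palette has {n_classes} classes)"
        )
    return mask


def encode_mask(mask: np.ndarray, palette: ClassPalette = DEFAULT_PALETTE) -> np.ndarray:
    """Render a class-index mask as a palette-colored RGB image."""
    mask = _validate_mask(mask, len(palette))
    return palette.color_array[mask]


def decode_mask(image: np.ndarray, palette: ClassPalette = DEFAULT_PALETTE) -> np.ndarray:
    """Recover class indices from RGB by nearest palette color.

    Total function: every pixel is assigned the class whose palette color has
    the minimum Euclidean distance in RGB space; ties go to the lowest class
    index. This quantizes the generator's continuous RGB output.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    px = image.astype(np.int32)
    colors = palette.color_array.astype(np.int32)
    # (H, W, K) squared distances; argmin breaks ties toward lower index
    d2 = ((px[:, :, None, :] - colors[None, None, :, :]) ** 2).sum(axis=-1)
    return d2.argmin(axis=2).astype(np.uint8)


# ---------------------------------------------------------------------------
# file I/O


def _world_file_path(path: str) -> str:
    base, ext = os.path.splitext(path)
    ext = ext.lower().lstrip(".")
    if len(ext) >= 3:
        side = ext[0] + ext[-1] + "w"  # .png -> .pgw, .tif -> .tfw
    else:
        side = ext + "w"
    return base + "." + side


def _read_world_file(path: str) -> GeoRef:
    with open(path) as fh:
        vals = [float(line.strip()) for line in fh if line.strip()]
    if len(vals) != 6:
        raise ValueError(f"world file {path} must have 6 numeric lines")
    a, d, b, e, c, f = vals
    if d != 0 or b != 0:
        raise ValueError("rotated world files are not supported")
    if not (a > 0 and e < 0):
        raise ValueError("expected positive x scale and negative y scale")
    if abs(a + e) > 1e-9 * abs(a):
        raise ValueError("non-square pixels are not supported")
    # world files give the CENTER of the top-left pixel
    return GeoRef(gsd=a, origin=(c - a / 2.0, f - e / 2.0))


def _write_world_file(path: str, georef: GeoRef) -> None:
    g = georef.gsd
    cx = georef.origin[0] + g / 2.0
    cy = georef.origin[1] - g / 2.0
    with open(path, "w") as fh:
        fh.write(f"{g:.12g}\n0.0\n0.0\n{-g:.12g}\n{cx:.12g}\n{cy:.12g}\n")


def write_raster(raster: GeoRaster, path: str) -> None:
    """Write a raster as GeoTIFF (.tif/.tiff) or PNG (+ world file if georeferenced).

    GeoTIFF carries gsd/origin in pixel-scale and tiepoint tags and the CRS in
    a JSON ImageDescription; round-trips are lossless for 8-bit content.
    """
    data = np.ascontiguousarray(raster.data.astype(np.uint8))
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        extratags = []
        desc = None
        if raster.georef is not None:
            g = raster.georef
            extratags = [
                (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.gsd, g.gsd, 0.0)),
                (_TAG_MODEL_TIEPOINT, "d", 6,
                 (0.0, 0.0, 0.0, g.origin[0], g.origin[1], 0.0)),
            ]
            desc = json.dumps({"crs": g.crs})
        tifffile.imwrite(path, data, description=desc, extratags=extratags,
                         photometric="rgb" if data.ndim == 3 else "minisblack")
    elif ext == ".png":
        Image.fromarray(data, mode="RGB" if data.ndim == 3 else "L").save(path)
        if raster.georef is not None:
            _write_world_file(_world_file_path(path), raster.georef)
    else:
        raise ValueError(f"unsupported raster format {ext!r} (use .tif or .png)")


def read_raster(path: str) -> GeoRaster:
    """Read a GeoTIFF or PNG raster; georeference is attached when available.

    A PNG (or plain TIFF) with no sidecar world file yields a GeoRaster whose
    ``georef`` is None; area operations on it fail loudly later.
    """
    ext = os.path.splitext(path)[1].lower()
    georef = None
    if ext in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            tags = page.tags
            if _TAG_MODEL_PIXEL_SCALE in tags and _TAG_MODEL_TIEPOINT in tags:
                scale = tags[_TAG_MODEL_PIXEL_SCALE].value
                tie = tags[_TAG_MODEL_TIEPOINT].value
                crs = None
                if "ImageDescription" in tags:
                    try:
                        crs = json.loads(tags["ImageDescription"].value).get("crs")
                    except (ValueError, AttributeError):
                        crs = None
                # tiepoint maps raster (i, j, k) -> model (x, y, z)
                ox = tie[3] - tie[0] * scale[0]
                oy = tie[4] + tie[1] * scale[1]
                georef = GeoRef(gsd=float(scale[0]), origin=(ox, oy), crs=crs)
    elif ext == ".png":
        data = np.asarray(Image.open(path))
        wf = _world_file_path(path)
        if os.path.exists(wf):
            georef = _read_world_file(wf)
    else:
        raise ValueError(f"unsupported raster format {ext!r} (use .tif or .png)")
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[2] == 4:  # drop alpha if present
        data = data[:, :, :3]
    return GeoRaster(data=data.astype(np.uint8), georef=georef)
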