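"""Overlapping-window tiling of orthophotos and mosaic reassembly.

Very-high-resolution scenes are divided into square windows (default 256 px)
with a configurable overlap (default 50%), segmented tile by tile, and the
per-tile label masks are fused back into a full-scene mask by per-pixel
majority vote. Edges are handled by reflection padding so the tile grid always
ends exactly at the (padded) image border; the reassembled mask is cropped
back to the original size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["TileSpec", "TileGrid", "plan_tiles", "extract_tiles", "reassemble",
           "write_tile_set"]

#: overlap-resolution priority: sargassum wins ties over sand over other,
#: favoring recall of the positive class
DEFAULT_PRIORITY = (2, 1, 0)


@dataclass(frozen=True)
class TileSpec:
    """Window geometry: tile edge length and fractional overlap.

    The stride ``tile_size * (1 - overlap_fraction)`` must come out a positive
    integer; 256 px tiles at 50% overlap (stride 128) is the default.
    """

    tile_size: int = 256
    overlap_fraction: float = 0.5

    def __post_init__(self):
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        s = self.tile_size * (1.0 - self.overlap_fraction)
        if abs(s - round(s)) > 1e-9 or round(s) < 1:
            raise ValueError(
                f"tile_size {self.tile_size} with overlap {self.overlap_fraction} "
                f"gives non-integer stride {s}"
            )

    @property
    def stride(self) -> int:
        return int(round(self.tile_size * (1.0 - self.overlap_fraction)))


@dataclass(frozen=True)
class TileGrid:
    """Planned tile layout for one scene (origins in padded coordinates)."""

    height: int                 # original scene height
    width: int                  # original scene width
    padded_height: int
    padded_width: int
    tile_size: int
    stride: int
    origins: tuple              # row-major ((row, col), ...)

    @property
    def n_tiles(self) -> int:
        return len(self.origins)

    def coverage_counts(self) -> np.ndarray:
        """Number of tiles covering each original pixel (>= 1 everywhere)."""
        cov = np.zeros((self.padded_height, self.padded_width), dtype=np.int32)
        t = self.tile_size
        for r, c in self.origins:
            cov[r:r + t, c:c + t] += 1
        return cov[: self.height, : self.width]

    def to_dict(self) -> dict:
        return {
            "height": self.height, "width": self.width,
            "padded_height": self.padded_height, "padded_width": self.padded_width,
            "tile_size": self.tile_size, "stride": self.stride,
            "origins": [list(o) for o in self.origins],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TileGrid":
        return cls(height=d["height"], width=d["width"],
                   padded_height=d["padded_height"], padded_width=d["padded_width"],
                   tile_size=d["tile_size"], stride=d["stride"],
                   origins=tuple(tuple(o) for o in d["origins"]))


def _padded_extent(dim: int, tile: int, stride: int) -> int:
    """Smallest value >= dim of the form tile + k*stride, k >= 0."""
    if dim <= tile:
        return tile
    k = -(-(dim - tile) // stride)  # ceil
    return tile + k * stride


def plan_tiles(height: int, width: int, spec: TileSpec = TileSpec()) -> TileGrid:
    """Plan a full Cartesian grid of overlapping windows covering the scene."""
    if height < 1 or width < 1:
        raise ValueError("scene dimensions must be >= 1")
    t, s = spec.tile_size, spec.stride
    ph = _padded_extent(height, t, s)
    pw = _padded_extent(width, t, s)
    rows = range(0, ph - t + 1, s)
    cols = range(0, pw - t + 1, s)
    origins = tuple((r, c) for r in rows for c in cols)
    return TileGrid(height=height, width=width, padded_height=ph,
                    padded_width=pw, tile_size=t, stride=s, origins=origins)


def _reflect_pad(arr: np.ndarray, pad_h: int, pad_w: int) -> np.ndarray:
    """Reflection-pad the two leading axes, chunked so any pad size works."""
    out = arr
    while pad_h > 0 or pad_w > 0:
        ch = min(pad_h, max(out.shape[0] - 1, 1))
        cw = min(pad_w, max(out.shape[1] - 1, 1))
        mode = "reflect" if min(out.shape[0], out.shape[1]) > 1 else "edge"
        widths = ((0, ch), (0, cw)) + ((0, 0),) * (out.ndim - 2)
        out = np.pad(out, widths, mode=mode)
        pad_h -= ch
        pad_w -= cw
    return out


def extract_tiles(data: np.ndarray, grid: TileGrid) -> List[np.ndarray]:
    """Cut the planned windows out of a scene (image or mask), row-major.

    The scene is reflection-padded to the grid's padded extent first, so every
    tile has the full tile size.
    """
    data = np.asarray(data)
    if data.shape[0] != grid.height or data.shape[1] != grid.width:
        raise ValueError(
            f"scene shape {data.shape[:2]} does not match grid "
            f"({grid.height}, {grid.width})"
        )
    padded = _reflect_pad(data, grid.padded_height - grid.height,
                          grid.padded_width - grid.width)
    t = grid.tile_size
    return [padded[r:r + t, c:c + t].copy() for r, c in grid.origins]


def reassemble(tiles: Sequence[np.ndarray], grid: TileGrid,
               n_classes: int = 3,
               priority: Tuple[int, ...] = DEFAULT_PRIORITY) -> np.ndarray:
    """Fuse per-tile label masks into one scene mask by majority vote.

    Every pixel takes the class with the most votes among the tiles covering
    it; ties are broken by the fixed priority order (default sargassum > sand
    > other). The result is cropped back to the original scene size.
    """
    if len(tiles) != grid.n_tiles:
        raise ValueError(f"expected {grid.n_tiles} tiles, got {len(tiles)}")
    t = grid.tile_size
    votes = np.zeros((n_classes, grid.padded_height, grid.padded_width),
                     dtype=np.int32)
    for (r, c), tile in zip(grid.origins, tiles):
        tile = np.asarray(tile)
        if tile.shape != (t, t):
            raise ValueError(f"tile at ({r},{c}) has shape {tile.shape}, "
                             f"expected ({t},{t})")
        for k in range(n_classes):
            votes[k, r:r + t, c:c + t] += tile == k
    if sorted(priority) != list(range(n_classes)):
        raise ValueError("priority must be a permutation of the class indices")
    out = np.zeros((grid.padded_height, grid.padded_width), dtype=np.uint8)
    best = np.full(out.shape, -1, dtype=np.int32)
    for k in priority:  # earlier entries win ties (strict > afterwards)
        better = votes[k] > best
        out[better] = k
        best[better] = votes[k][better]
    return out[: grid.height, : grid.width]


def write_tile_set(tiles, grid: TileGrid, out_dir: str, scene: str,
                   source_bytes: bytes = b"") -> str:
    """Write tiles as ``{scene}_{row}_{col}.png`` plus a JSON grid manifest.

    Returns the manifest path. The manifest records the grid geometry and a
    checksum of the source scene so reassembly never has to guess.
    """
    import os
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for (r, c), tile in zip(grid.origins, tiles):
        p = os.path.join(out_dir, f"{scene}_{r}_{c}.png")
        arr = np.asarray(tile, dtype=np.uint8)
        Image.fromarray(arr, mode="RGB" if arr.ndim == 3 else "L").save(p)
        paths.append(os.path.basename(p))
    manifest = {
        "scene": scene,
        "grid": grid.to_dict(),
        "tiles": paths,
        "source_sha256": hashlib.sha256(source_bytes).hexdigest(),
    }
    mp = os.path.join(out_dir, f"{scene}_tiles.json")
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return mp
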