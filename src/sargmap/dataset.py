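"""Paired-sample assembly, 80/20 splitting, and dataset characterization.

A training example is a 256x256 RGB tile paired with its label mask. The
dataset is described by two statistics that drive how hard it is to learn
from: the Shannon entropy of each tile's gray-level histogram (beach scenes
are dominated by homogeneous water/sand areas, so low-entropy tiles dominate)
and the per-class pixel counts (strong class imbalance, with sargassum the
rarest class).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .raster_io import ClassPalette, DEFAULT_PALETTE, decode_mask

__all__ = [
    "PairedSample", "SplitConfig", "ImageStats",
    "shannon_entropy", "class_pixel_counts", "split_dataset", "dataset_report",
    "write_manifest", "load_pairs",
]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PairedSample:
    """One (source image, target mask) training pair."""

    source: np.ndarray          # (H, W, 3) uint8
    target: np.ndarray          # (H, W) uint8 class indices
    id: str = ""

    def __post_init__(self):
        self.source = np.asarray(self.source)
        self.target = np.asarray(self.target)
        if self.source.shape[:2] != self.target.shape:
            raise ValueError(
                f"source {self.source.shape[:2]} and target "
                f"{self.target.shape} dimensions differ for sample {self.id!r}"
            )


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ImageStats:
    """Per-sample statistics: entropy and class composition."""

    entropy_bits: float
    class_pixels: np.ndarray
    p: np.ndarray               # 256-bin gray-level relative frequencies


def shannon_entropy(image: np.ndarray) -> float:
    """Shannon entropy (bits) of the 8-bit gray-level histogram.

    RGB input is converted to BT.601 luminance (rounded to the nearest
    integer) first; a 2-D input is treated as already gray. The result lies in
    [0, 8] for 8-bit data: 0 for a constant image, 8 for a uniform spread over
    all 256 levels. Zero-probability bins contribute nothing.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        gray = np.rint(image.astype(np.float64) @ _LUMA)
        gray = np.clip(gray, 0, 255).astype(np.uint8)
    else:
        gray = image.astype(np.uint8)
    counts = np.bincount(gray.ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def class_pixel_counts(mask: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Pixel tally per class index; sums to H*W."""
    mask = np.asarray(mask)
    if mask.size and mask.max() >= n_classes:
        raise ValueError(f"label {int(mask.max())} >= n_classes {n_classes}")
    return np.bincount(mask.ravel(), minlength=n_classes)


def split_dataset(n: int, config: SplitConfig = SplitConfig()
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test index split, deterministic per seed.

    The train size is ``floor(n * train_fraction)``; with the canonical
    n=15,268 at 0.8 this gives the 12,214/3,054 partition.
    """
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * config.train_fraction))
    return perm[:n_train], perm[n_train:]


def sample_stats(sample: PairedSample, n_classes: int = 3) -> ImageStats:
    gray = np.rint(sample.source.astype(np.float64) @ _LUMA)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    counts = np.bincount(gray.ravel(), minlength=256)
    p = counts / counts.sum()
    nz = p[p > 0]
    return ImageStats(
        entropy_bits=float(-(nz * np.log2(nz)).sum()),
        class_pixels=class_pixel_counts(sample.target, n_classes),
        p=p,
    )


def dataset_report(samples: Sequence[PairedSample], n_classes: int = 3,
                   entropy_bins: int = 32) -> dict:
    """Aggregate entropy and class-composition report over a sample set.

    Returns per-sample records, the entropy histogram over [0, 8] bits, the
    mean entropy, per-class pixel-fraction histograms, and total pixel counts
    per class. Deterministic; suitable for JSON serialization.
    """
    if len(samples) == 0:
        raise ValueError("dataset_report needs at least one sample")
    records = []
    entropies = []
    totals = np.zeros(n_classes, dtype=np.int64)
    fracs = []
    for s in samples:
        st = sample_stats(s, n_classes)
        entropies.append(st.entropy_bits)
        totals += st.class_pixels
        fracs.append(st.class_pixels / st.class_pixels.sum())
        records.append({
            "id": s.id,
            "entropy_bits": st.entropy_bits,
            "class_pixels": [int(v) for v in st.class_pixels],
        })
    entropies = np.asarray(entropies)
    fracs = np.asarray(fracs)
    ent_hist, ent_edges = np.histogram(entropies, bins=entropy_bins, range=(0.0, 8.0))
    class_hists = {}
    for k in range(n_classes):
        h, e = np.histogram(fracs[:, k], bins=20, range=(0.0, 1.0))
        class_hists[k] = {"counts": [int(v) for v in h],
                          "edges": [float(v) for v in e]}
    return {
        "n_samples": len(samples),
        "mean_entropy_bits": float(entropies.mean()),
        "entropy_histogram": {"counts": [int(v) for v in ent_hist],
                              "edges": [float(v) for v in ent_edges]},
        "class_pixel_totals": [int(v) for v in totals],
        "class_fraction_histograms": class_hists,
        "samples": records,
    }


def write_manifest(path: str, records: Sequence[dict]) -> None:
    """Write a JSON-lines dataset manifest (one record per pair)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_manifest(path: str) -> List[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def load_pairs(manifest_path: str, palette: ClassPalette = DEFAULT_PALETTE,
               split: Optional[str] = None) -> List[PairedSample]:
    """Load paired samples listed in a manifest (paths relative to it).

    Targets stored as palette-encoded RGB PNGs are decoded to class indices;
    single-band PNGs are taken as index masks directly. ``split`` filters on
    the manifest's ``split`` field when given.
    """
    import os
    from PIL import Image

    base = os.path.dirname(os.path.abspath(manifest_path))
    pairs = []
    for rec in read_manifest(manifest_path):
        if split is not None and rec.get("split") != split:
            continue
        src = np.asarray(Image.open(os.path.join(base, rec["image"])))[..., :3]
        tgt = np.asarray(Image.open(os.path.join(base, rec["mask"])))
        if tgt.ndim == 3:
            tgt = decode_mask(tgt[..., :3], palette)
        pairs.append(PairedSample(source=src, target=tgt, id=rec.get("id", "")))
    return pairs
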