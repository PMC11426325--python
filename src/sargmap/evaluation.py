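"""Pixel-level evaluation: confusion matrices, precision/recall/f-beta,
robust summaries, and bootstrap confidence intervals.

Per evaluated image a K x K confusion matrix of pixel counts is formed (rows
= predicted class, columns = ground truth). From each class's row/column,
precision = TP/(TP+FP) and recall = TP/(TP+FN), combined by

    f_beta = (1 + beta^2) * precision * recall / (beta^2 * precision + recall)

with beta = 0.5 weighting precision (penalizes false positives — sargassum
over-detection) and beta = 2 weighting recall (penalizes false negatives —
missed sargassum). beta = 0 degenerates to precision. The three-class matrix
can be merged to a binary sargassum-vs-rest matrix by summing the sand and
other rows/columns.

Zero-denominator conventions (images frequently lack a class entirely): if a
class is absent from both prediction and truth the metric is 1; if absent
only on the denominator's side it is 0. Either way the record is flagged
degenerate so summary statistics can include or exclude it by policy.

Uncertainty on dataset-level means is quantified by a seeded percentile
bootstrap (default 2,000 resamples, 90% interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfusionMatrix", "MetricRecord", "SummaryStats", "BootstrapResult",
    "confusion_matrix", "merge_to_binary", "precision", "recall", "fbeta",
    "evaluate_pairs", "bootstrap_ci", "summarize",
]

MERGED_CLASS_NAMES = ("other", "sargassum")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K pixel-count table; rows = predicted, columns = ground truth."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix counts must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(pred: np.ndarray, truth: np.ndarray,
                     k: int = 3) -> ConfusionMatrix:
    """Per-pixel tally: counts[r, c] = #pixels predicted r with truth c."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.size and (pred.max() >= k or truth.max() >= k):
        raise ValueError(f"labels must be < k={k}")
    flat = pred.astype(np.int64).ravel() * k + truth.astype(np.int64).ravel()
    counts = np.bincount(flat, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


def merge_to_binary(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Unify sand and other into one negative class; order [other, sargassum].

    Row/column sums are conserved, so binary metrics for sargassum computed
    from the merged matrix equal the three-class ones exactly.
    """
    if cm.k != 3:
        raise ValueError("merge_to_binary expects a 3x3 matrix")
    c = cm.counts
    neg = (0, 1)  # other + sand
    merged = np.array([
        [c[np.ix_(neg, neg)].sum(), c[neg, 2].sum()],
        [c[2, neg].sum(),           c[2, 2]],
    ], dtype=np.int64)
    return ConfusionMatrix(merged)


def _prf(cm: ConfusionMatrix, cls: int) -> Tuple[float, float, bool]:
    """(precision, recall, degenerate_flag) for one class."""
    c = cm.counts
    tp = int(c[cls, cls])
    pred_pos = int(c[cls, :].sum())
    true_pos = int(c[:, cls].sum())
    degenerate = pred_pos == 0 or true_pos == 0
    if pred_pos == 0 and true_pos == 0:
        return 1.0, 1.0, True
    p = tp / pred_pos if pred_pos else 0.0
    r = tp / true_pos if true_pos else 0.0
    return p, r, degenerate


def precision(cm: ConfusionMatrix, cls: int) -> float:
    """TP / (TP + FP) over the class's predicted row."""
    return _prf(cm, cls)[0]


def recall(cm: ConfusionMatrix, cls: int) -> float:
    """TP / (TP + FN) over the class's ground-truth column."""
    return _prf(cm, cls)[1]


def fbeta(p: float, r: float, beta: float) -> float:
    """Weighted harmonic combination of precision and recall.

    beta = 0 returns precision; p = r = 0 returns 0 by convention.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if beta == 0:
        return p
    denom = beta * beta * p + r
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * p * r / denom


@dataclass
class MetricRecord:
    """Per-image, per-class precision/recall/f-beta values with flags."""

    id: str
    precision: Dict[int, float]
    recall: Dict[int, float]
    fbeta: Dict[float, Dict[int, float]]   # beta -> class -> value
    degenerate: Dict[int, bool]

    def macro_fbeta(self, beta: float) -> float:
        vals = self.fbeta[beta]
        return float(np.mean(list(vals.values())))


@dataclass(frozen=True)
class SummaryStats:
    """Mean / sample sd / median / (raw) MAD / max of one metric."""

    mean: float
    sd: float
    median: float
    mad: float
    max: float
    n: int

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "median": self.median,
                "mad": self.mad, "max": self.max, "n": self.n}


def summarize(values: Sequence[float], mad_scale: float = 1.0) -> SummaryStats:
    """Table-style summary; MAD is raw unless ``mad_scale`` (e.g. 1.4826)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    v = np.sort(v)  # fixed summation order: summaries are exactly
    med = float(np.median(v))  # permutation-invariant in image order
    return SummaryStats(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=med,
        mad=float(np.median(np.abs(v - med))) * mad_scale,
        max=float(v.max()),
        n=int(v.size),
    )


def evaluate_pairs(preds: Sequence[np.ndarray], truths: Sequence[np.ndarray],
                   betas: Sequence[float] = (0.5, 2.0), k: int = 3,
                   ids: Optional[Sequence[str]] = None,
                   exclude_degenerate: bool = False,
                   mad_scale: float = 1.0
                   ) -> Tuple[List[MetricRecord], Dict[str, Dict]]:
    """Per-image metric records plus per-class and macro summary statistics.

    Degenerate (absent-class) records are included as their flagged
    conventional values by default; ``exclude_degenerate`` drops that class's
    values from the summaries instead.
    """
    if len(preds) == 0 or len(preds) != len(truths):
        raise ValueError("need equal, non-empty prediction and truth sequences")
    ids = ids or [str(i) for i in range(len(preds))]
    records: List[MetricRecord] = []
    for pid, pred, truth in zip(ids, preds, truths):
        cm = confusion_matrix(pred, truth, k)
        prec, rec, deg = {}, {}, {}
        for cls in range(k):
            p, r, d = _prf(cm, cls)
            prec[cls], rec[cls], deg[cls] = p, r, d
        fb = {float(b): {cls: fbeta(prec[cls], rec[cls], b) for cls in range(k)}
              for b in betas}
        records.append(MetricRecord(id=pid, precision=prec, recall=rec,
                                    fbeta=fb, degenerate=deg))

    def collect(getter, cls):
        vals = []
        for rec in records:
            if exclude_degenerate and rec.degenerate[cls]:
                continue
            vals.append(getter(rec, cls))
        return vals

    summaries: Dict[str, Dict] = {}
    for cls in range(k):
        entry = {
            "precision": summarize(
                collect(lambda r, c: r.precision[c], cls) or [np.nan],
                mad_scale).as_dict(),
            "recall": summarize(
                collect(lambda r, c: r.recall[c], cls) or [np.nan],
                mad_scale).as_dict(),
        }
        for b in betas:
            entry[f"f{b:g}"] = summarize(
                collect(lambda r, c: r.fbeta[float(b)][c], cls) or [np.nan],
                mad_scale).as_dict()
        summaries[f"class_{cls}"] = entry
    macro = {}
    for b in betas:
        macro[f"f{b:g}"] = summarize(
            [r.macro_fbeta(float(b)) for r in records], mad_scale).as_dict()
    summaries["macro"] = macro
    return records, summaries


@dataclass(frozen=True)
class BootstrapResult:
    point_mean: float
    ci_low: float
    ci_high: float
    level: float
    n_resamples: int
    seed: int

    def as_dict(self) -> dict:
        return {"point_mean": self.point_mean, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "level": self.level,
                "n_resamples": self.n_resamples, "seed": self.seed}


def bootstrap_ci(values: Sequence[float], n_resamples: int = 2000,
                 level: float = 0.90, seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap CI for the mean, deterministic per seed.

    Each resample draws the original sample size with replacement; the
    interval is the (1-level)/2 and 1-(1-level)/2 quantiles of the resampled
    means (5th/95th percentiles at the default 90% level).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("bootstrap needs at least 2 values")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_resamples, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapResult(point_mean=float(v.mean()), ci_low=float(lo),
                           ci_high=float(hi), level=level,
                           n_resamples=n_resamples, seed=seed)
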