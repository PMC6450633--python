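"""Localization metrics: coverage and hit rate over box sets.

Both metrics are pixel-level set measures on the rasterized unions of the
proposed and ground-truth boxes:

    coverage = N_pixel(proposed ∩ ground) / N_pixel(ground)
    hit rate = N_pixel(proposed ∩ ground) / N_pixel(proposed)

i.e. coverage is recall of ground-truth pixels and hit rate is precision of
proposed pixels.  An image with no ground boxes has undefined coverage (and
no proposals means undefined hit rate); such images are excluded from the
dataset aggregation and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .localization import Box


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator set is empty."""


@dataclass
class BoxSet:
    boxes: list = field(default_factory=list)
    image_dims: tuple = (128, 342)

    def __post_init__(self):
        h, w = self.image_dims
        for b in self.boxes:
            if not (0 <= b.row_min < b.row_max <= h and 0 <= b.col_min < b.col_max <= w):
                raise ValueError(f"box {b} outside image dims {(h, w)}")


def rasterize_union(bs: BoxSet) -> np.ndarray:
    """Boolean mask of pixels inside at least one box (union semantics)."""
    mask = np.zeros(bs.image_dims, dtype=bool)
    for b in bs.boxes:
        mask[b.row_min:b.row_max, b.col_min:b.col_max] = True
    return mask


def coverage(proposed: BoxSet, ground: BoxSet) -> float:
    """Fraction of ground-truth pixels recovered by the proposals."""
    if proposed.image_dims != ground.image_dims:
        raise ValueError("box sets live on different image dims")
    gmask = rasterize_union(ground)
    denom = int(gmask.sum())
    if denom == 0:
        raise UndefinedMetricError("empty ground-truth box set")
    inter = int((rasterize_union(proposed) & gmask).sum())
    return inter / denom


def hit_rate(proposed: BoxSet, ground: BoxSet) -> float:
    """Fraction of proposed pixels that are ground truth."""
    if proposed.image_dims != ground.image_dims:
        raise ValueError("box sets live on different image dims")
    pmask = rasterize_union(proposed)
    denom = int(pmask.sum())
    if denom == 0:
        raise UndefinedMetricError("empty proposed box set")
    inter = int((pmask & rasterize_union(ground)).sum())
    return inter / denom


def evaluate_dataset(per_image) -> pd.DataFrame:
    """Mean/std of coverage and hit rate over (proposed, ground) pairs.

    Images whose metric is undefined are excluded from that metric's mean
    and reported in ``n_excluded``.  Raises if every image is undefined for
    both metrics.
    """
    if len(per_image) == 0:
        raise ValueError("no images to evaluate")
    values = {"coverage": [], "hit_rate": []}
    excluded = {"coverage": 0, "hit_rate": 0}
    for proposed, ground in per_image:
        for name, fn in (("coverage", coverage), ("hit_rate", hit_rate)):
            try:
                values[name].append(fn(proposed, ground))
            except UndefinedMetricError:
                excluded[name] += 1
    if not values["coverage"] and not values["hit_rate"]:
        raise ValueError("all images have undefined metrics")
    rows = []
    for name in ("coverage", "hit_rate"):
        v = np.asarray(values[name], dtype=float)
        rows.append(
            {
                "metric": name,
                "mean": float(v.mean()) if v.size else float("nan"),
                "std": float(v.std()) if v.size else float("nan"),
                "n": int(v.size),
                "n_excluded": excluded[name],
            }
        )
    return pd.DataFrame(rows)
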