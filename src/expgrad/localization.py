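"""From attribution maps to lesion proposals.

The localization recipe: keep the positive part of the attribution, reduce
channels, min-max normalize to [0, 1], threshold at tau (default 0.3), grow
a disc of fixed radius around every hot pixel, merge overlapping discs into
connected components, and box each component.  Boxes are scored by the sum
of heat inside the rectangle and ranked so clinicians can view the top-k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .attribution import InputAttribution, normalize01

F32 = np.float32


@dataclass
class Box:
    """Axis-aligned rectangle in 0-based, half-open pixel coordinates."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int
    score: float = 0.0

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(f"degenerate box {self!r}")
        if self.score < 0:
            raise ValueError("box score must be >= 0")

    @property
    def pixel_count(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)

    def to_dict(self):
        return {
            "row_min": int(self.row_min),
            "col_min": int(self.col_min),
            "row_max": int(self.row_max),
            "col_max": int(self.col_max),
            "score": float(self.score),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            int(d["row_min"]), int(d["col_min"]), int(d["row_max"]), int(d["col_max"]),
            float(d.get("score", 0.0)),
        )


@dataclass
class LocalizationConfig:
    """tau: heat threshold (strict >); radius: disc radius in pixels grown
    around each hot pixel; top_k: box count to keep ('all' keeps every box);
    channel_reduce: how RGB attribution channels collapse to one heat value.
    """

    tau: float = 0.3
    radius: int = 10
    top_k: object = "all"
    channel_reduce: str = "mean"


def heat_from_attribution(att, cfg: LocalizationConfig | None = None) -> np.ndarray:
    """Positive part -> channel reduction -> min-max normalization to [0,1]."""
    cfg = cfg or LocalizationConfig()
    vals = att.values if isinstance(att, InputAttribution) else np.asarray(att)
    vals = np.clip(vals, 0, None).astype(F32)
    if vals.ndim == 3:
        reducer = {"mean": np.mean, "sum": np.sum, "max": np.max}[cfg.channel_reduce]
        vals = reducer(vals, axis=2)
    return normalize01(vals)


def threshold_pixels(heat: np.ndarray, tau: float) -> np.ndarray:
    """Hot-pixel mask: strictly greater than tau."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must be in [0, 1]")
    return heat > tau


def propose_boxes(mask: np.ndarray, heat: np.ndarray, cfg: LocalizationConfig | None = None):
    """Disc-grow hot pixels, merge into connected components, box and score.

    Returns boxes sorted by (score desc, row_min, col_min)."""
    cfg = cfg or LocalizationConfig()
    if mask.shape != heat.shape:
        raise ValueError("mask and heat must share dimensions")
    if not mask.any():
        return []
    grown = ndimage.binary_dilation(mask, structure=disk(cfg.radius))
    labels, n = ndimage.label(grown, structure=np.ones((3, 3), dtype=int))
    boxes = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        boxes.append(Box(r0, c0, r1, c1, float(heat[r0:r1, c0:c1].sum())))
    boxes.sort(key=lambda b: (-b.score, b.row_min, b.col_min))
    return boxes


def top_k(boxes, k):
    """First min(k, len) boxes under the (score desc, top-left) ordering."""
    if isinstance(k, str) and k == "all":
        k = len(boxes)
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(boxes, key=lambda b: (-b.score, b.row_min, b.col_min))
    return ordered[: min(k, len(ordered))]


def spatial_shuffle(heat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Null model for localization: the same heat values at random positions."""
    flat = heat.ravel().copy()
    rng.shuffle(flat)
    return flat.reshape(heat.shape)


def render_overlay(image: np.ndarray, heat: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Blend a colormapped heat over the image, weighted by alpha * heat so
    cold regions keep the original pixels.  Pure function."""
    import matplotlib

    if image.shape[:2] != heat.shape:
        raise ValueError("image and heat dimensions differ")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    cmap = matplotlib.colormaps["jet"]
    color = cmap(heat.astype(np.float64))[..., :3].astype(F32)
    w = (alpha * heat)[..., None].astype(F32)
    return image * (1 - w) + color * w


def render_boxes(image: np.ndarray, boxes, color=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Draw 1-pixel rectangle outlines; box interiors untouched.  Pure."""
    h, w = image.shape[:2]
    out = image.copy()
    color = np.asarray(color, dtype=F32)
    for b in boxes:
        if not (0 <= b.row_min < b.row_max <= h and 0 <= b.col_min < b.col_max <= w):
            raise ValueError(f"box {b} out of image bounds {(h, w)}")
        out[b.row_min, b.col_min:b.col_max] = color
        out[b.row_max - 1, b.col_min:b.col_max] = color
        out[b.row_min:b.row_max, b.col_min] = color
        out[b.row_min:b.row_max, b.col_max - 1] = color
    return out
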