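"""File-format glue: images, dataset manifests, box annotations."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .evaluation import BoxSet
from .localization import Box
from .model import ClassLabel

F32 = np.float32


def load_image(path, target_shape=None) -> np.ndarray:
    """Read PNG/JPEG/TIFF as float RGB in [0,1]; bilinear-resize to the
    model's (height, width) if the file has different dimensions."""
    img = PILImage.open(path).convert("RGB")
    if target_shape is not None:
        th, tw = target_shape[:2]
        if img.size != (tw, th):
            img = img.resize((tw, th), PILImage.BILINEAR)
    return np.asarray(img, dtype=F32) / 255.0


def save_image(path, image: np.ndarray):
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    PILImage.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def save_dataset(samples, out_dir) -> Path:
    """Write PNGs, a ``manifest.csv`` (path, label_name) and an
    ``annotations.json`` with every ground-truth box."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, annotations = [], {}
    for i, s in enumerate(samples):
        name = f"sample_{i:05d}.png"
        save_image(out_dir / name, s.image)
        rows.append({"path": name, "label_name": s.label.name})
        annotations[name] = {
            "class": s.label.name,
            "image_dims": list(s.gt_boxes.image_dims),
            "boxes": [b.to_dict() for b in s.gt_boxes.boxes],
        }
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "annotations.json").write_text(json.dumps(annotations, indent=2))
    return out_dir / "manifest.csv"


def load_manifest(manifest_path, input_shape):
    """Load (image, label) pairs listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    pairs = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = root / p
        try:
            img = load_image(p, target_shape=input_shape)
        except Exception as exc:
            raise IOError(f"cannot read image {p}: {exc}") from exc
        pairs.append((img, ClassLabel.from_name(row["label_name"])))
    return pairs


def save_boxes_json(path, image_name, class_name, boxes, image_dims):
    payload = {
        "image": str(image_name),
        "class": class_name,
        "image_dims": list(image_dims),
        "boxes": [b.to_dict() for b in boxes],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_boxes_json(path) -> dict:
    """Read either a single-image box file or a multi-image annotation file
    into {image_name: BoxSet}."""
    data = json.loads(Path(path).read_text())
    if "boxes" in data:  # single image
        data = {data["image"]: data}
    out = {}
    for name, entry in data.items():
        dims = tuple(entry.get("image_dims", (128, 342)))
        out[name] = BoxSet([Box.from_dict(b) for b in entry["boxes"]], dims)
    return out


def save_boxes_csv(path, boxes):
    pd.DataFrame([b.to_dict() for b in boxes]).to_csv(path, index=False)


def save_attribution(path, values: np.ndarray, metadata: dict | None = None):
    """Export an attribution map as 32-bit float TIFF (``.tif``/``.tiff``)
    or an NPZ container, with a JSON sidecar holding the metadata
    (method, layer, betas, steps, target class, ...)."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, values, photometric="minisblack")
    else:
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        np.savez(path, values=values)
    path.with_suffix(".json").write_text(json.dumps(metadata or {}, indent=2))
    return path


def load_attribution(path):
    """Read a map written by :func:`save_attribution`; returns (values, metadata)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        values = tifffile.imread(path)
    else:
        values = np.load(path)["values"]
    sidecar = path.with_suffix(".json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, metadata
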