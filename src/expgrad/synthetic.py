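"""OCT-like phantom images with implanted, exactly-annotated lesions.

A phantom is a dark background crossed by one bright, smoothly curved
horizontal band (a cartoon of the retinal layer complex in a macular
B-scan), rendered identically in all three RGB channels plus additive
Gaussian noise.  Lesions are implanted per class:

* ``dry_amd`` — 1-4 small bright bumps on the band's lower edge
  (drusen-like deposits);
* ``wet_amd_observation`` — 1-2 small dark elliptical cavities inside the
  band (fluid pockets);
* ``wet_amd_injection`` — 2-4 larger cavities plus one broad bright dome
  under the band (detachment-like distortion);
* ``normal`` — no lesions.

Every lesion's tight bounding box is recorded, so localization can be
scored against exact ground truth.  The geometry is analytic and seeded:
the generator exists to make the pipeline testable, not to imitate OCT
speckle physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import BoxSet
from .localization import Box
from .model import ClassLabel

F32 = np.float32


@dataclass
class PhantomConfig:
    dims: tuple = (128, 342)
    background_level: float = 0.05
    band_peak: float = 0.8
    band_sigma: float = 7.0       # Gaussian cross-section of the band, px
    band_amplitude: float = 18.0  # centerline curvature amplitude, px
    noise_sigma: float = 0.02
    lesion_count_range: dict = field(
        default_factory=lambda: {
            "dry_amd": (1, 4),
            "wet_amd_observation": (1, 2),
            "wet_amd_injection": (2, 4),
        }
    )
    # (rows, cols) half-axis ranges, px
    dry_radius: tuple = ((3, 6), (3, 7))
    obs_radius: tuple = ((3, 6), (4, 9))
    inj_radius: tuple = ((5, 8), (8, 14))
    seed: int = 0

    def __post_init__(self):
        h, _ = self.dims
        if 6 * self.band_sigma >= h:
            raise ValueError("band does not fit inside the image height")

    @classmethod
    def scaled(cls, dims, seed: int = 0, **overrides) -> "PhantomConfig":
        """Config for non-default dims with band and lesion geometry scaled
        proportionally from the 128 x 342 reference resolution."""
        f = dims[0] / 128.0
        g = dims[1] / 342.0

        def srange(pair, factor):
            lo, hi = pair
            return (max(1.0, lo * factor), max(2.0, hi * factor))

        defaults = cls()
        params = dict(
            dims=tuple(dims),
            band_sigma=max(1.5, defaults.band_sigma * f),
            band_amplitude=max(1.0, defaults.band_amplitude * f),
            dry_radius=(srange(defaults.dry_radius[0], f), srange(defaults.dry_radius[1], g)),
            obs_radius=(srange(defaults.obs_radius[0], f), srange(defaults.obs_radius[1], g)),
            inj_radius=(srange(defaults.inj_radius[0], f), srange(defaults.inj_radius[1], g)),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class SyntheticSample:
    image: np.ndarray
    label: ClassLabel
    gt_boxes: BoxSet


def _centerline(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Random low-order polynomial centerline, one row value per column."""
    h, w = cfg.dims
    t = np.linspace(-1.0, 1.0, w)
    c0 = h * rng.uniform(0.42, 0.58)
    c1 = rng.uniform(-cfg.band_amplitude, cfg.band_amplitude)
    c2 = rng.uniform(-cfg.band_amplitude, cfg.band_amplitude)
    y = c0 + c1 * t + c2 * (t * t - 0.5)
    margin = 3.0 * cfg.band_sigma + 4
    return np.clip(y, margin, h - margin)


def _render(cfg: PhantomConfig, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.dims
    rows = np.arange(h, dtype=F32)[:, None]
    band = cfg.band_peak * np.exp(-((rows - center[None, :]) ** 2) / (2 * cfg.band_sigma**2))
    gray = cfg.background_level + band
    if cfg.noise_sigma > 0:
        gray = gray + rng.normal(0.0, cfg.noise_sigma, size=(h, w))
    gray = np.clip(gray, 0.0, 1.0).astype(F32)
    return np.repeat(gray[:, :, None], 3, axis=2)


def generate_background(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Lesion-free phantom: dark background + one bright curved band + noise."""
    return _render(cfg, _centerline(cfg, rng), rng)


def band_centerline_from_image(image: np.ndarray) -> np.ndarray:
    """Recover the band's row position per column (argmax of intensity)."""
    return image[:, :, 0].argmax(axis=0)


def _clip_box(h, w, r0, c0, r1, c1) -> Box:
    return Box(max(0, r0), max(0, c0), min(h, r1), min(w, c1))


def implant_lesions(
    image: np.ndarray, label: ClassLabel, cfg: PhantomConfig, rng: np.random.Generator
) -> SyntheticSample:
    """Implant class-dependent lesions; record tight ground-truth boxes."""
    h, w = cfg.dims
    img = image.copy()
    center = band_centerline_from_image(image)
    boxes = []
    rr = np.arange(h, dtype=F32)[:, None]
    cc = np.arange(w, dtype=F32)[None, :]

    def bump(row, col, ry, rx, amp):
        g = amp * np.exp(-(((rr - row) / ry) ** 2 + ((cc - col) / rx) ** 2))
        np.clip(img + g[:, :, None], 0.0, 1.0, out=img)
        boxes.append(_clip_box(h, w, int(row - ry), int(col - rx), int(row + ry) + 1, int(col + rx) + 1))

    def cavity(row, col, ry, rx, depth):
        # superellipse profile: flat dark core, sharp edge
        d2 = ((rr - row) / ry) ** 2 + ((cc - col) / rx) ** 2
        img[...] *= (1.0 - depth * np.exp(-(d2**2)))[:, :, None].astype(F32)
        boxes.append(_clip_box(h, w, int(row - ry), int(col - rx), int(row + ry) + 1, int(col + rx) + 1))

    def lesion_col():
        return int(rng.uniform(0.08, 0.92) * w)

    name = ClassLabel(label).name
    if name != "normal":
        lo, hi = cfg.lesion_count_range[name]
        n_lesions = int(rng.integers(lo, hi + 1))
        if name == "dry_amd":
            (ry0, ry1), (rx0, rx1) = cfg.dry_radius
            for _ in range(n_lesions):
                col = lesion_col()
                ry = rng.uniform(ry0, ry1)
                rx = rng.uniform(rx0, rx1)
                row = center[col] + cfg.band_sigma
                bump(row, col, ry, rx, amp=rng.uniform(0.35, 0.55))
        else:
            rad = cfg.obs_radius if name == "wet_amd_observation" else cfg.inj_radius
            (ry0, ry1), (rx0, rx1) = rad
            for _ in range(n_lesions):
                col = lesion_col()
                ry = rng.uniform(ry0, ry1)
                rx = rng.uniform(rx0, rx1)
                cavity(center[col], col, ry, rx, depth=rng.uniform(0.7, 0.9))
            if name == "wet_amd_injection":
                # broad bright dome under the band: detachment-like distortion
                col = lesion_col()
                ry = rng.uniform(6, 10)
                rx = rng.uniform(15, 25)
                bump(center[col] + 1.6 * cfg.band_sigma, col, ry, rx, amp=rng.uniform(0.25, 0.40))
    return SyntheticSample(image=img, label=ClassLabel(label), gt_boxes=BoxSet(boxes, (h, w)))


def generate_sample(label: ClassLabel, cfg: PhantomConfig, rng: np.random.Generator) -> SyntheticSample:
    return implant_lesions(generate_background(cfg, rng), label, cfg, rng)


# class mix mirroring the 5075 / 2225 / 650 / 2150 clinical class counts
DEFAULT_CLASS_MIX = (5075 / 10100, 2225 / 10100, 650 / 10100, 2150 / 10100)


def generate_dataset(
    n: int,
    class_mix: tuple = DEFAULT_CLASS_MIX,
    cfg: PhantomConfig | None = None,
    stratified: bool = False,
) -> list:
    """Draw ``n`` phantoms with labels per ``class_mix`` (seeded by cfg.seed).

    ``stratified=True`` deals labels round-robin in exact proportion instead
    of multinomial sampling."""
    cfg = cfg or PhantomConfig()
    if n < 4:
        raise ValueError("n must be >= 4")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-6 or (mix < 0).any():
        raise ValueError(f"class_mix must be 4 non-negative fractions summing to 1, got {class_mix}")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n + 1)
    label_rng = np.random.default_rng(children[0])
    if stratified:
        counts = np.floor(mix * n).astype(int)
        while counts.sum() < n:
            counts[int(np.argmax(mix * n - counts))] += 1
        labels = np.repeat(np.arange(4), counts)
        label_rng.shuffle(labels)
    else:
        labels = label_rng.choice(4, size=n, p=mix)
    samples = []
    for child, lab in zip(children[1:], labels):
        rng = np.random.default_rng(child)
        samples.append(generate_sample(ClassLabel(int(lab)), cfg, rng))
    return samples
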