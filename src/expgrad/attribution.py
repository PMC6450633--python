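"""Gradient-based attribution: Integrated Gradients, layer-wise attribution,
projection to input dimensions, the Expressive Gradients fusion, and guided
backpropagation.

Integrated Gradients attributes the class score F_c(x) to input pixels as

    IG(x) = (x - b) * mean_k  dF_c(b + (k/S)(x - b)) / dx ,   k = 1..S

a right-endpoint Riemann approximation of the path integral from the
baseline b (a black image by default) to x.  The layer-wise variant applies
the same construction to the feature map f_i of conv layer i, with the
partial network F_{i+1} (all layers after conv i) as the scoring function
and the baseline's own feature map b_i as the path start.

A layer attribution lives in feature-map coordinates; it is projected back
to input coordinates by walking towards the input: across each conv layer
the channels are mixed by the kernel-marginalized weight matrix
wg[c_out, c_in] = sum over kernel positions of W[c_out, c_in, :, :] (with a
1-pixel zero pad to undo 'valid' convs), and across each pooling layer the
map is copy-unpooled (every value replicated over its receptive 2x2 block).

Expressive Gradients fuses all levels:

    EG = sum_{i=0..L}  beta_i * N( project( EG_i(f_i) ) )

where N is whole-map 0-to-1 min-max normalization.  The default weights are
beta = [1, 0.166, 0.166, 0.166, 0.166, 0.166, 1]: full weight on the input
map (fine detail) and the deepest map (semantic localization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ClassLabel, Model

F32 = np.float32

DEFAULT_BETAS = (1.0, 0.166, 0.166, 0.166, 0.166, 0.166, 1.0)


@dataclass
class BaselineSpec:
    """Integration-path start; 'black' is the all-zeros image."""

    kind: str = "black"  # black | custom
    custom_image: np.ndarray | None = None

    def image(self, input_shape) -> np.ndarray:
        if self.kind == "black":
            return np.zeros(input_shape, dtype=F32)
        if self.custom_image is None:
            raise ValueError("custom baseline requires custom_image")
        return np.asarray(self.custom_image, dtype=F32)


@dataclass
class EGConfig:
    """Attribution configuration.

    betas: per-level fusion weights, length L+1 (input level + L conv
        layers).  None selects the defaults for a 6-conv model.
    steps: Riemann-sum discretization of the path integral (default 50).
    layer_baseline: 'forward' takes b_i as the baseline image's own feature
        map at layer i; 'zeros' uses an all-zero feature map.
    target_class: 'predicted' (argmax) or an explicit class.
    level_norm: what N() normalizes per level during fusion — the signed
        projected map ('signed', the default) or only its positive part
        ('positive', matching the localization rule that discards negative
        pixels; keeps a large negative outlier from lifting the whole map).
    step_chunk: internal batch size for the path points.
    """

    betas: tuple | None = None
    steps: int = 50
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    target_class: object = "predicted"
    layer_baseline: str = "forward"
    level_norm: str = "signed"  # signed | positive
    step_chunk: int = 8

    def resolved_betas(self, num_conv_layers: int):
        betas = DEFAULT_BETAS if self.betas is None else tuple(self.betas)
        if len(betas) != num_conv_layers + 1:
            raise ValueError(
                f"betas length {len(betas)} != num_conv_layers + 1 = {num_conv_layers + 1}"
            )
        return betas


@dataclass
class LayerAttribution:
    layer_index: int
    values: np.ndarray


@dataclass
class InputAttribution:
    values: np.ndarray


@dataclass
class ProjectionMatrix:
    values: np.ndarray
    layer_index: int | None = None


def _resolve_target(model: Model, scores: np.ndarray, cfg: EGConfig) -> int:
    t = cfg.target_class
    if isinstance(t, str) and t == "predicted":
        return int(np.argmax(scores))
    return int(t)


def _path_average_gradient(model, start_pos, f, b, steps, target, chunk):
    """Mean gradient of the target score along the straight path b -> f,
    right-endpoint rule (alpha = k/steps, k = 1..steps)."""
    delta = (f - b).astype(F32)
    total = np.zeros_like(delta)
    alphas = (np.arange(1, steps + 1, dtype=F32)) / F32(steps)
    for lo in range(0, steps, chunk):
        a = alphas[lo : lo + chunk]
        batch = b[None] + a.reshape((-1,) + (1,) * delta.ndim) * delta[None]
        out = model._run(batch.astype(F32), start_pos=start_pos)
        dy = np.zeros_like(out)
        dy[:, target] = 1.0
        g = model._grad_input(dy, start_pos=start_pos)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradients in suffix from position {start_pos}")
        total += g.sum(axis=0)
    return total / F32(steps), delta


def _layer_ig(model, i, feats, b_feats, steps, target, chunk):
    f_i = feats[i]
    b_i = b_feats[i]
    avg_grad, delta = _path_average_gradient(
        model, model.suffix_start(i), f_i, b_i, steps, target, chunk
    )
    return LayerAttribution(layer_index=i, values=delta * avg_grad)


def _baseline_features(model, image, cfg: EGConfig):
    b_img = cfg.baseline.image(model.input_shape)
    if cfg.layer_baseline == "zeros":
        _, feats = model.forward(image)  # only for shapes
        return b_img, [b_img] + [np.zeros_like(f) for f in feats[1:]]
    _, b_feats = model.forward(b_img)
    return b_img, b_feats


def integrated_gradients(model: Model, image: np.ndarray, cfg: EGConfig | None = None) -> InputAttribution:
    """Input-level Integrated Gradients for the target class."""
    cfg = cfg or EGConfig()
    if cfg.steps < 1:
        raise ValueError("steps must be >= 1")
    scores, feats = model.forward(image)
    target = _resolve_target(model, scores, cfg)
    b_img = cfg.baseline.image(model.input_shape)
    avg_grad, delta = _path_average_gradient(
        model, 0, feats[0], b_img, cfg.steps, target, cfg.step_chunk
    )
    return InputAttribution(values=delta * avg_grad)


def layer_integrated_gradients(model: Model, i: int, image: np.ndarray, cfg: EGConfig | None = None) -> LayerAttribution:
    """Layer-wise attribution EG_i(f_i); i = 0 coincides with plain IG."""
    cfg = cfg or EGConfig()
    if not 0 <= i <= model.num_conv_layers:
        raise ValueError(f"layer index {i} out of range 0..{model.num_conv_layers}")
    scores, feats = model.forward(image)
    target = _resolve_target(model, scores, cfg)
    _, b_feats = _baseline_features(model, image, cfg)
    return _layer_ig(model, i, feats, b_feats, cfg.steps, target, cfg.step_chunk)


def marginalize_weights(omega: np.ndarray, layer_index: int | None = None) -> ProjectionMatrix:
    """Collapse a conv kernel over its spatial positions:
    wg[c_out, c_in] = sum_{kh,kw} omega[c_out, c_in, kh, kw]."""
    omega = np.asarray(omega)
    if omega.ndim != 4 or omega.shape[2] != omega.shape[3]:
        raise ValueError("expected a rank-4 conv weight tensor with a square kernel")
    return ProjectionMatrix(values=omega.sum(axis=(2, 3)), layer_index=layer_index)


def unpool_copy(att: np.ndarray, factor: int) -> np.ndarray:
    """Index-free unpooling: replicate each spatial cell over a factor x
    factor block (channels unchanged)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return att.copy()
    return np.repeat(np.repeat(att, factor, axis=0), factor, axis=1)


def _fit_spatial(att: np.ndarray, target_hw) -> np.ndarray:
    """Crop or zero-pad (bottom/right) to the recorded pre-pool dims."""
    th, tw = target_hw
    att = att[:th, :tw]
    ph, pw = th - att.shape[0], tw - att.shape[1]
    if ph or pw:
        pad = [(0, ph), (0, pw)] + [(0, 0)] * (att.ndim - 2)
        att = np.pad(att, pad)
    return att


def project_attribution(model: Model, att: LayerAttribution) -> InputAttribution:
    """Walk a layer attribution back to input dimensions (copy-unpool across
    pooling, kernel-marginalized channel mixing across convs)."""
    from . import nnlayers as nn

    i = att.layer_index
    if i < 0:
        raise ValueError("layer_index must be >= 0")
    vals = np.asarray(att.values, dtype=F32)
    if i == 0:
        return InputAttribution(values=vals.copy())
    end = model.conv_positions[i - 1]
    for pos in range(end, -1, -1):
        layer = model.layers[pos]
        if isinstance(layer, nn.Conv2D):
            wg = layer.params["W"].sum(axis=(2, 3))  # (d_out, d_in)
            vals = np.tensordot(vals, wg, axes=([2], [0]))
            if layer.pad == "valid":
                vals = np.pad(vals, ((1, 1), (1, 1), (0, 0)))
        elif isinstance(layer, nn.MaxPool2):
            vals = unpool_copy(vals, layer.factor)
            vals = _fit_spatial(vals, layer.in_hw)
        elif isinstance(layer, (nn.BatchNorm2D, nn.Dropout)):
            pass  # channel-preserving; identity in the projection walk
        else:
            raise RuntimeError(f"unexpected layer {type(layer).__name__} in the conv trunk")
    if vals.shape != tuple(model.input_shape):
        raise RuntimeError(
            f"projection produced shape {vals.shape}, expected {model.input_shape}"
        )
    return InputAttribution(values=vals)


def cumulative_projection_matrix(model: Model, i: int) -> ProjectionMatrix:
    """W_i = wg_i @ wg_{i-1} @ ... @ wg_1, shape (d_i, d_0).

    Equals the stepwise projection for pool-free, same-padding models; kept
    as an independent cross-check of the stepwise walk."""
    W = None
    for l in range(1, i + 1):
        wg = marginalize_weights(model.conv_weights(l), l).values
        W = wg if W is None else wg @ W
    return ProjectionMatrix(values=W, layer_index=i)


def normalize01(att: np.ndarray) -> np.ndarray:
    """Whole-map min-max scaling to [0, 1]; constant maps map to zeros."""
    att = np.asarray(att, dtype=F32)
    lo = float(att.min())
    hi = float(att.max())
    if hi - lo <= 0:
        return np.zeros_like(att)
    return (att - lo) / (hi - lo)


def expressive_gradients(model: Model, image: np.ndarray, cfg: EGConfig | None = None) -> InputAttribution:
    """Fused multi-level attribution EG = sum_i beta_i * N(project(EG_i))."""
    cfg = cfg or EGConfig()
    L = model.num_conv_layers
    betas = cfg.resolved_betas(L)
    scores, feats = model.forward(image)
    target = _resolve_target(model, scores, cfg)
    _, b_feats = _baseline_features(model, image, cfg)
    if cfg.level_norm not in ("signed", "positive"):
        raise ValueError(f"unknown level_norm {cfg.level_norm!r}")
    total = np.zeros(model.input_shape, dtype=F32)
    for i in range(L + 1):
        if betas[i] == 0:
            continue
        att_i = _layer_ig(model, i, feats, b_feats, cfg.steps, target, cfg.step_chunk)
        vals = project_attribution(model, att_i).values
        if cfg.level_norm == "positive":
            vals = np.clip(vals, 0, None)
        total += F32(betas[i]) * normalize01(vals)
    return InputAttribution(values=total)


def guided_backpropagation(model: Model, image: np.ndarray, target_class=None) -> InputAttribution:
    """Single backward pass with ReLU gating: the backward signal is zeroed
    wherever the forward activation or the incoming signal is negative."""
    scores, feats = model.forward(image)
    if target_class is None:
        target = int(np.argmax(scores))
    else:
        target = int(target_class)
    x = feats[0][None]
    out = model._run(x)  # fresh eval forward to populate caches
    dy = np.zeros_like(out)
    dy[:, target] = 1.0
    g = model._grad_input(dy, guided=True)
    return InputAttribution(values=g[0])


__all__ = [
    "BaselineSpec",
    "EGConfig",
    "LayerAttribution",
    "InputAttribution",
    "ProjectionMatrix",
    "DEFAULT_BETAS",
    "integrated_gradients",
    "layer_integrated_gradients",
    "marginalize_weights",
    "unpool_copy",
    "project_attribution",
    "cumulative_projection_matrix",
    "normalize01",
    "expressive_gradients",
    "guided_backpropagation",
]
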