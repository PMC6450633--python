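"""Attribution: IG axioms, layer-wise maps, projection, fusion, GBP."""

import numpy as np
import pytest

from expgrad.attribution import (
    EGConfig,
    LayerAttribution,
    cumulative_projection_matrix,
    expressive_gradients,
    guided_backpropagation,
    integrated_gradients,
    layer_integrated_gradients,
    marginalize_weights,
    normalize01,
    project_attribution,
    unpool_copy,
)
from expgrad.model import LayerSpec, ModelSpec, build_model, default_model_spec
from conftest import TOY_DIMS, toy_spec

F32 = np.float32


def linear_model(num_out=4):
    """flatten -> dense with no activation: F(x) = W^T x + b, b = 0."""
    spec = ModelSpec(
        input_shape=(4, 5, 3),
        layers=[LayerSpec("flatten"), LayerSpec("dense", num_out, activation="none")],
    )
    return build_model(spec, seed=11)


def poolfree_spec():
    return ModelSpec(
        input_shape=(10, 12, 3),
        layers=[
            LayerSpec("conv_same", 5, activation="relu"),
            LayerSpec("conv_same", 6, activation="relu"),
            LayerSpec("flatten"),
            LayerSpec("dense", 2, activation="sigmoid"),
        ],
    )


# -- integrated gradients --------------------------------------------------

def test_linear_model_ig_closed_form(rng):
    """For linear F with zero baseline, IG is exactly w * x."""
    m = linear_model()
    x = rng.random(m.input_shape).astype(F32)
    att = integrated_gradients(m, x, EGConfig(steps=7, target_class=2))
    w = m.layers[-1].params["W"][:, 2].reshape(m.input_shape)
    np.testing.assert_allclose(att.values, w * x, atol=1e-6)


def test_ig_at_baseline_is_zero(toy_model):
    black = np.zeros(toy_model.input_shape, dtype=F32)
    att = integrated_gradients(toy_model, black, EGConfig(steps=5, target_class=0))
    np.testing.assert_array_equal(att.values, 0)
    for i in range(1, toy_model.num_conv_layers + 1):
        la = layer_integrated_gradients(toy_model, i, black, EGConfig(steps=5, target_class=0))
        np.testing.assert_array_equal(la.values, 0)


def test_ig_completeness(toy_model, toy_test_data):
    """Sum of attributions approximates F_c(x) - F_c(black)."""
    img = toy_test_data[0].image
    scores, _ = toy_model.forward(img)
    c = int(scores.argmax())
    b_scores, _ = toy_model.forward(np.zeros_like(img))
    delta_f = scores[c] - b_scores[c]
    att = integrated_gradients(toy_model, img, EGConfig(steps=300, target_class=c))
    gap = abs(att.values.sum() - delta_f) / abs(delta_f)
    assert gap < 0.01


def test_layer_ig_index0_equals_ig(toy_model, toy_test_data):
    img = toy_test_data[1].image
    cfg = EGConfig(steps=20)
    a = integrated_gradients(toy_model, img, cfg)
    b = layer_integrated_gradients(toy_model, 0, img, cfg)
    assert b.layer_index == 0
    np.testing.assert_allclose(a.values, b.values, atol=1e-7)


def test_layer_ig_completeness_on_suffix(toy_model, toy_test_data):
    """EG_1 satisfies completeness for the partial model taking f_1."""
    img = toy_test_data[2].image
    scores, feats = toy_model.forward(img)
    c = int(scores.argmax())
    _, b_feats = toy_model.forward(np.zeros_like(img))
    la = layer_integrated_gradients(toy_model, 1, img, EGConfig(steps=500, target_class=c))
    delta_f = (
        toy_model.partial_forward(1, feats[1])[c]
        - toy_model.partial_forward(1, b_feats[1])[c]
    )
    assert abs(la.values.sum() - delta_f) / abs(delta_f) < 0.02


def test_ig_monotone_refinement(toy_model, toy_test_data):
    """Doubling the Riemann steps yields a Cauchy-shrinking L1 delta."""
    img = toy_test_data[3].image
    maps = {
        s: integrated_gradients(toy_model, img, EGConfig(steps=s, target_class=1)).values
        for s in (10, 20, 40, 80)
    }
    d1 = np.abs(maps[20] - maps[10]).sum()
    d2 = np.abs(maps[40] - maps[20]).sum()
    d3 = np.abs(maps[80] - maps[40]).sum()
    assert d2 < d1 and d3 < d2


def test_ig_rejects_bad_steps(toy_model, toy_test_data):
    with pytest.raises(ValueError):
        integrated_gradients(toy_model, toy_test_data[0].image, EGConfig(steps=0))


# -- weight marginalization and unpooling ----------------------------------

def test_marginalize_examples():
    ones = np.ones((2, 3, 3, 3))
    np.testing.assert_array_equal(marginalize_weights(ones).values, np.full((2, 3), 9.0))
    k = np.arange(1, 10, dtype=float).reshape(1, 1, 3, 3)
    assert marginalize_weights(k).values[0, 0] == 45.0
    with pytest.raises(ValueError):
        marginalize_weights(np.ones((2, 3, 3)))


def test_marginalize_matches_bruteforce(rng):
    for _ in range(20):
        omega = rng.standard_normal((8, 4, 3, 3))
        wg = marginalize_weights(omega).values
        brute = np.zeros((8, 4))
        for co in range(8):
            for ci in range(4):
                for a in range(3):
                    for b in range(3):
                        brute[co, ci] += omega[co, ci, a, b]
        np.testing.assert_allclose(wg, brute, rtol=1e-12)


def test_unpool_copy():
    v = np.array([[3.0]])
    np.testing.assert_array_equal(unpool_copy(v, 2), np.full((2, 2), 3.0))
    m = np.arange(6.0).reshape(2, 3)
    up = unpool_copy(m, 2)
    assert up.shape == (4, 6)
    for i in range(2):
        for j in range(3):
            assert (up[2 * i:2 * i + 2, 2 * j:2 * j + 2] == m[i, j]).all()
    np.testing.assert_array_equal(unpool_copy(m, 1), m)


# -- projection ------------------------------------------------------------

def test_project_layer0_identity(rng):
    m = build_model(toy_spec(), seed=0)
    vals = rng.standard_normal(m.input_shape).astype(F32)
    out = project_attribution(m, LayerAttribution(0, vals))
    np.testing.assert_array_equal(out.values, vals)


def test_project_single_conv_hand_computed(rng):
    """Ones attribution through one same-pad conv: channel c collapses to
    sum_co wg[co, c] everywhere."""
    spec = ModelSpec(
        input_shape=(6, 7, 3),
        layers=[
            LayerSpec("conv_same", 4, activation="relu"),
            LayerSpec("flatten"),
            LayerSpec("dense", 2, activation="sigmoid"),
        ],
    )
    m = build_model(spec, seed=5)
    att = LayerAttribution(1, np.ones((6, 7, 4), dtype=F32))
    out = project_attribution(m, att).values
    wg = m.conv_weights(1).sum(axis=(2, 3))  # (4, 3)
    expected = wg.sum(axis=0)
    for c in range(3):
        np.testing.assert_allclose(out[:, :, c], expected[c], rtol=1e-5)


@pytest.mark.parametrize("i", [1, 2, 3, 4, 5, 6])
def test_project_default_model_shape_contract(i, rng):
    m = build_model(default_model_spec(), seed=0)
    shape = m.shape_trace[m.conv_positions[i - 1]]
    att = LayerAttribution(i, rng.standard_normal(shape).astype(F32))
    out = project_attribution(m, att)
    assert out.values.shape == (128, 342, 3)


def test_stepwise_projection_equals_cumulative_product(rng):
    """On a pool-free model the walk equals one W_i = wg_i ... wg_1 product."""
    m = build_model(poolfree_spec(), seed=3)
    shape = m.shape_trace[m.conv_positions[1]]
    vals = rng.standard_normal(shape).astype(F32)
    stepwise = project_attribution(m, LayerAttribution(2, vals)).values
    W2 = cumulative_projection_matrix(m, 2).values  # (6, 3)
    direct = np.tensordot(vals, W2, axes=([2], [0]))
    np.testing.assert_allclose(stepwise, direct, atol=1e-5)


# -- normalization and fusion ----------------------------------------------

def test_normalize01():
    np.testing.assert_allclose(normalize01(np.array([0.0, 5.0, 10.0])), [0, 0.5, 1])
    np.testing.assert_array_equal(normalize01(np.full((3, 3), 7.0)), 0)
    out = normalize01(np.array([[-2.0, 3.0], [1.0, 0.5]]))
    assert out.min() == 0 and out.max() == 1


def test_eg_reduces_to_ig_with_e0_betas(toy_model, toy_test_data):
    cfg = EGConfig(betas=(1, 0, 0), steps=10)
    for s in toy_test_data[:3]:
        eg = expressive_gradients(toy_model, s.image, cfg)
        ig = integrated_gradients(toy_model, s.image, EGConfig(steps=10))
        np.testing.assert_allclose(eg.values, normalize01(ig.values), atol=1e-6)


def test_eg_all_zero_betas(toy_model, toy_test_data):
    eg = expressive_gradients(toy_model, toy_test_data[0].image, EGConfig(betas=(0, 0, 0), steps=5))
    np.testing.assert_array_equal(eg.values, 0)


def test_eg_matches_compositional_oracle(toy_model, toy_test_data):
    """EG equals the explicit per-level sum of its sub-operations."""
    img = toy_test_data[4].image
    betas = (1.0, 0.166, 1.0)
    cfg = EGConfig(betas=betas, steps=12)
    eg = expressive_gradients(toy_model, img, cfg)
    scores, _ = toy_model.forward(img)
    c = int(scores.argmax())
    total = np.zeros(toy_model.input_shape, dtype=F32)
    for i, beta in enumerate(betas):
        la = layer_integrated_gradients(toy_model, i, img, EGConfig(steps=12, target_class=c))
        total += F32(beta) * normalize01(project_attribution(toy_model, la).values)
    np.testing.assert_allclose(eg.values, total, atol=1e-6)


def test_eg_betas_length_validated(toy_model, toy_test_data):
    with pytest.raises(ValueError):
        expressive_gradients(toy_model, toy_test_data[0].image, EGConfig(betas=(1, 0)))


def test_eg_deterministic(toy_model, toy_test_data):
    img = toy_test_data[5].image
    cfg = EGConfig(betas=(1, 0.5, 1), steps=8)
    a = expressive_gradients(toy_model, img, cfg)
    b = expressive_gradients(toy_model, img, cfg)
    np.testing.assert_array_equal(a.values, b.values)


# -- guided backpropagation ------------------------------------------------

def test_gbp_linear_model_equals_gradient(rng):
    m = linear_model()
    x = rng.random(m.input_shape).astype(F32)
    g = guided_backpropagation(m, x, target_class=1)
    w = m.layers[-1].params["W"][:, 1].reshape(m.input_shape)
    np.testing.assert_allclose(g.values, w, atol=1e-6)


def test_gbp_zero_image_dead_relu_net():
    m = build_model(toy_spec(), seed=2)  # untrained: zero biases
    g = guided_backpropagation(m, np.zeros(m.input_shape, dtype=F32), target_class=0)
    np.testing.assert_array_equal(g.values, 0)


def test_gbp_matches_manual_gating(rng):
    """Two-dense-layer net: explicit ReLU-gated backward computation."""
    spec = ModelSpec(
        input_shape=(2, 3, 3),
        layers=[
            LayerSpec("flatten"),
            LayerSpec("dense", 6, activation="relu"),
            LayerSpec("dense", 2, activation="sigmoid"),
        ],
    )
    m = build_model(spec, seed=8)
    x = rng.standard_normal(m.input_shape).astype(F32)
    g = guided_backpropagation(m, x, target_class=0)
    W1, b1 = m.layers[1].params["W"], m.layers[1].params["b"]
    W2 = m.layers[2].params["W"]
    z1 = x.reshape(-1) @ W1 + b1
    a1 = np.maximum(z1, 0)
    s = 1 / (1 + np.exp(-(a1 @ W2 + m.layers[2].params["b"])))
    dz2 = np.array([s[0] * (1 - s[0]), 0.0], dtype=F32)
    da1 = dz2 @ W2.T
    gated = np.where((a1 > 0) & (da1 > 0), da1, 0)
    expected = (gated @ W1.T).reshape(m.input_shape)
    np.testing.assert_allclose(g.values, expected, atol=1e-6)
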