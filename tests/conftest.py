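"""Shared fixtures: small phantom configs and a trained toy CNN.

The toy problem lives at 32 x 86 pixels — the same band-plus-lesion
geometry as the full-size phantoms, scaled so that training and 300-step
path integrals run in seconds.
"""

import numpy as np
import pytest

from expgrad.model import (
    LayerSpec,
    ModelSpec,
    TrainConfig,
    build_model,
    train_model,
)
from expgrad.synthetic import PhantomConfig, generate_dataset

TOY_DIMS = (32, 86)


def small_phantom_cfg(seed=0):
    return PhantomConfig(
        dims=TOY_DIMS,
        band_sigma=3.0,
        band_amplitude=4.0,
        dry_radius=((2, 3), (2, 4)),
        obs_radius=((2, 3), (3, 5)),
        inj_radius=((3, 5), (5, 8)),
        seed=seed,
    )


def toy_spec(channels=(8, 8), num_classes=4):
    """2-conv + 1-dense CNN on the small phantom dims."""
    return ModelSpec(
        input_shape=TOY_DIMS + (3,),
        layers=[
            LayerSpec("conv_same", channels[0], activation="relu"),
            LayerSpec("conv_valid", channels[1], activation="relu"),
            LayerSpec("maxpool"),
            LayerSpec("flatten"),
            LayerSpec("dense", num_classes, activation="sigmoid"),
        ],
    )


BALANCED_MIX = (0.25, 0.25, 0.25, 0.25)


@pytest.fixture(scope="session")
def toy_train_data():
    return generate_dataset(
        200, class_mix=BALANCED_MIX, cfg=small_phantom_cfg(seed=42), stratified=True
    )


@pytest.fixture(scope="session")
def toy_test_data():
    return generate_dataset(
        60, class_mix=BALANCED_MIX, cfg=small_phantom_cfg(seed=43), stratified=True
    )


@pytest.fixture(scope="session")
def toy_model(toy_train_data):
    """The 2-conv toy CNN trained 20 epochs on 200 small phantoms."""
    model = build_model(toy_spec(), seed=42)
    cfg = TrainConfig(epochs_schedule=[(20, 2e-3)], batch_size=16, seed=42)
    model, _ = train_model(model, toy_train_data, cfg)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(0)
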