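"""Shared fixtures.

The desk-scale trained model is expensive (minutes of CPU training), so it
is built once per session and shared by every test that exercises a trained
generator (conditional recovery, blending, micro-structuring).
"""

from __future__ import annotations

import numpy as np
import pytest

from microstain import presets
from microstain.network import build_discriminator, build_generator
from microstain.synthetic_data import build_patch_dataset, make_dataset
from microstain.training import train

ACCEPTANCE_SEED = 11


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_manifests():
    return make_dataset(
        presets.DESK_TRAIN_SLIDES, seed=ACCEPTANCE_SEED, size=presets.DESK_SLIDE_SIZE
    )


@pytest.fixture(scope="session")
def trained_model(desk_manifests):
    """Desk-scale conditional GAN trained on the synthetic study conditions."""
    dataset = build_patch_dataset(
        desk_manifests["train"],
        patch=presets.DESK_PATCH,
        stride=presets.DESK_STRIDE,
        seed=ACCEPTANCE_SEED,
    )
    generator = build_generator(presets.desk_scale_generator_spec, seed=1)
    discriminator = build_discriminator(presets.desk_scale_discriminator_spec, seed=2)
    config = presets.desk_scale_training_config(seed=3)
    generator, history = train(dataset, generator, discriminator, config)
    return generator, history
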