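"""Frozen configurations: the full-scale reference schedule and a desk-scale study.

``reference_*`` mirror the published training conditions (four-level
generator, 64-channel discriminator stem, Adam at 1e-4/2e-6, ten generator
updates per discriminator step, batch 8, 21,000 discriminator steps on
256 x 256 patches) — a GPU-scale budget this package does not attempt to
run end-to-end.

``desk_scale_*`` define the package's CPU-scale study: a two-level,
8-channel generator on 64 x 64 patches, ~300 patches from 21 synthetic
training slides, 150 discriminator steps (1,500 generator updates).  The
learning rates are the reference rates scaled up to match the shortened
run: the reference schedule takes 210,000 generator updates at 1e-4, so a
1,500-update run uses 2e-3 (with the discriminator rate keeping the same
1:50 ratio) to give the optimizer a comparable total parameter
displacement.  These values are fixed once here; every end-to-end test and
the acceptance study use them unchanged.
"""

from __future__ import annotations

from .network import DiscriminatorSpec, GeneratorSpec
from .training import TrainingConfig

N_STAINS = 3

reference_generator_spec = GeneratorSpec(levels=4, base_channels=32, n_stains=N_STAINS)
reference_discriminator_spec = DiscriminatorSpec(
    patch_size=256, stem_channels=64, blocks=5, n_stains=N_STAINS
)


def reference_training_config(seed: int = 0) -> TrainingConfig:
    return TrainingConfig(total_discriminator_steps=21_000, seed=seed)


desk_scale_generator_spec = GeneratorSpec(levels=2, base_channels=8, n_stains=N_STAINS)
desk_scale_discriminator_spec = DiscriminatorSpec(
    patch_size=64, stem_channels=8, blocks=3, n_stains=N_STAINS
)

DESK_PATCH = 64
DESK_STRIDE = 32
DESK_TRAIN_SLIDES = 30  # 21 train / 4 val / 5 test after the split
DESK_SLIDE_SIZE = 192


def desk_scale_training_config(seed: int = 0) -> TrainingConfig:
    return TrainingConfig(
        lr_generator=2e-3,
        lr_discriminator=4e-5,
        total_discriminator_steps=150,
        seed=seed,
    )
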