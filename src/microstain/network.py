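"""Conditional generator and discriminator architectures.

The generator is a U-net: ``levels`` down-blocks (three 3x3 convolutions
with leaky-ReLU activations, the first of which doubles the channel count,
followed by 2x2 average pooling with stride 2) and matching up-blocks
(bilinear 2x upsampling, concatenation with the same-level down-block output
via a skip connection, then three convolutions that together reduce the
channel count by a factor of four), closed by a final 3x3 convolution down
to the three colour channels.  With stem width ``s`` the down-block outputs
carry s*2^l channels and every up-block concatenation sees exactly twice its
skip width, so the factor-of-four reduction reproduces the skip widths level
by level and the network is fully convolutional: the same weights run on any
spatial size divisible by 2^levels.

The discriminator receives six planes — the three YCbCr colour channels of
either the generator output or the real stained target, concatenated with
the staining-matrix planes — and maps them through a stem convolution, a
stack of blocks of two convolutions (the second doubling channels with
stride 2), a flatten, and two fully connected layers to a single sigmoid
score in (0, 1).  Because of the flatten it operates at a fixed patch size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (
    AvgPool2,
    BilinearUp2,
    Conv2D,
    Dense,
    Flatten,
    LeakyReLU,
    Param,
    Sigmoid,
    leaky_relu,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "leaky_relu",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Size parameters of the U-net generator.

    ``levels=4`` and ``base_channels=32`` is the full-scale configuration;
    desk-scale tests use (levels=2, base_channels=8).
    """

    levels: int = 4
    base_channels: int = 32
    n_stains: int = 3
    in_channels: int = 2  # autofluorescence channels before conditioning
    out_channels: int = 3
    convs_per_block: int = 3
    kernel: int = 3
    slope: float = 0.1

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    @property
    def total_in_channels(self) -> int:
        return self.in_channels + self.n_stains


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Size parameters of the conditional discriminator."""

    patch_size: int = 256
    stem_channels: int = 64
    blocks: int = 5
    n_stains: int = 3
    image_channels: int = 3
    kernel: int = 3
    slope: float = 0.1
    fc_hidden: int = 64

    def __post_init__(self) -> None:
        if self.blocks < 1:
            raise ValueError("blocks must be >= 1")
        if self.patch_size % (2**self.blocks) != 0:
            raise ValueError(
                f"patch size {self.patch_size} not divisible by 2^{self.blocks}"
            )

    @property
    def in_channels(self) -> int:
        return self.image_channels + self.n_stains


class Generator:
    """U-net mapping (N, H, W, 2 + n_stains) stacks to (N, H, W, 3) images."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.spec = spec
        s = spec.base_channels
        k = spec.kernel

        def conv(cin, cout, tag):
            return Conv2D(cin, cout, kernel=k, rng=rng, name=tag)

        self.stem = conv(spec.total_in_channels, s, "g.stem")
        self.stem_act = LeakyReLU(spec.slope)
        self.down_blocks: list[list] = []
        self.pools: list[AvgPool2] = []
        for lvl in range(1, spec.levels + 1):
            cin, cout = s * 2 ** (lvl - 1), s * 2**lvl
            block = [
                conv(cin, cout, f"g.down{lvl}.c1"), LeakyReLU(spec.slope),
                conv(cout, cout, f"g.down{lvl}.c2"), LeakyReLU(spec.slope),
                conv(cout, cout, f"g.down{lvl}.c3"), LeakyReLU(spec.slope),
            ]
            self.down_blocks.append(block)
            self.pools.append(AvgPool2())
        self.ups: list[BilinearUp2] = []
        self.up_blocks: list[list] = []
        for lvl in range(spec.levels, 0, -1):
            cat = 2 * s * 2**lvl  # upsampled path + same-width skip
            block = [
                conv(cat, cat // 2, f"g.up{lvl}.c1"), LeakyReLU(spec.slope),
                conv(cat // 2, cat // 4, f"g.up{lvl}.c2"), LeakyReLU(spec.slope),
                conv(cat // 4, cat // 4, f"g.up{lvl}.c3"), LeakyReLU(spec.slope),
            ]
            self.ups.append(BilinearUp2())
            self.up_blocks.append(block)
        self.final = conv(s, spec.out_channels, "g.final")

    def params(self) -> list[Param]:
        out = self.stem.params()
        for block in self.down_blocks + self.up_blocks:
            for layer in block:
                out += layer.params()
        return out + self.final.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        div = 2**self.spec.levels
        if h % div or w % div:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2^{self.spec.levels}"
            )
        if c != self.spec.total_in_channels:
            raise ValueError(
                f"expected {self.spec.total_in_channels} input channels, got {c}"
            )
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = self.stem_act.forward(self.stem.forward(x))
        skips = []
        for block, pool in zip(self.down_blocks, self.pools):
            for layer in block:
                y = layer.forward(y)
            skips.append(y)
            y = pool.forward(y)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.up_blocks, reversed(skips)):
            y = up.forward(y)
            self._skip_channels.append(skip.shape[3])
            y = np.concatenate([y, skip], axis=3)
            for layer in block:
                y = layer.forward(y)
        return self.final.forward(y)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.final.backward(grad.astype(np.float32))
        skip_grads = []
        for up, block, skc in zip(
            reversed(self.ups), reversed(self.up_blocks), reversed(self._skip_channels)
        ):
            for layer in reversed(block):
                grad = layer.backward(grad)
            grad, gskip = grad[..., :-skc], grad[..., -skc:]
            skip_grads.append(gskip)
            grad = up.backward(grad)
        skip_grads.reverse()  # now ordered bottom-level .. top-level
        for block, pool, gskip in zip(
            reversed(self.down_blocks), reversed(self.pools), skip_grads
        ):
            grad = pool.backward(grad) + gskip
            for layer in reversed(block):
                grad = layer.backward(grad)
        grad = self.stem.backward(self.stem_act.backward(grad))
        return grad


class Discriminator:
    """Conditional critic scoring (image, staining matrix) stacks in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.spec = spec
        k = spec.kernel
        self.layers: list = [
            Conv2D(spec.in_channels, spec.stem_channels, kernel=k, rng=rng, name="d.stem"),
            LeakyReLU(spec.slope),
        ]
        c = spec.stem_channels
        for b in range(spec.blocks):
            self.layers += [
                Conv2D(c, c, kernel=k, rng=rng, name=f"d.b{b}.c1"),
                LeakyReLU(spec.slope),
                Conv2D(c, 2 * c, kernel=k, stride=2, rng=rng, name=f"d.b{b}.c2"),
                LeakyReLU(spec.slope),
            ]
            c *= 2
        side = spec.patch_size // 2**spec.blocks
        self.layers += [
            Flatten(),
            Dense(side * side * c, spec.fc_hidden, rng=rng, name="d.fc1"),
            LeakyReLU(spec.slope),
            Dense(spec.fc_hidden, 1, rng=rng, name="d.fc2"),
            Sigmoid(),
        ]

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out += layer.params()
        return out

    def forward(self, image: np.ndarray, condition: np.ndarray) -> np.ndarray:
        """Score a batch; returns shape (N,) values strictly in (0, 1)."""
        if image.shape[:3] != condition.shape[:3]:
            raise ValueError(
                f"image {image.shape} and staining matrix {condition.shape} disagree"
            )
        if image.shape[1] != self.spec.patch_size or image.shape[2] != self.spec.patch_size:
            raise ValueError(
                f"discriminator operates on fixed {self.spec.patch_size}-px patches, "
                f"got {image.shape[1]}x{image.shape[2]}"
            )
        y = np.concatenate(
            [image.astype(np.float32), condition.astype(np.float32)], axis=3
        )
        for layer in self.layers:
            y = layer.forward(y)
        return y[:, 0]

    def backward(self, grad_score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backprop d(loss)/d(score); returns (grad_image, grad_condition)."""
        grad = grad_score.reshape(-1, 1).astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        nc = self.spec.image_channels
        return grad[..., :nc], grad[..., nc:]


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    """Construct a generator with seeded truncated-normal initialization."""
    return Generator(spec, rng=np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Checkpoints: spec + weights + stain-name ordering


def save_checkpoint(
    path: str | Path,
    generator: Generator,
    stain_names: list[str],
    discriminator: Discriminator | None = None,
    extra: dict | None = None,
) -> None:
    """Persist spec, weights and stain ordering to a single .npz file."""
    path = Path(path)
    meta = {
        "generator_spec": generator.spec.__dict__,
        "stain_names": list(stain_names),
        "discriminator_spec": discriminator.spec.__dict__ if discriminator else None,
        "extra": extra or {},
    }
    arrays = {f"g{i}": p.value for i, p in enumerate(generator.params())}
    if discriminator is not None:
        arrays.update({f"d{i}": p.value for i, p in enumerate(discriminator.params())})
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(
    path: str | Path, expect_stain_names: list[str] | None = None
) -> tuple[Generator, list[str], Discriminator | None]:
    """Load a checkpoint; refuses one whose stain ordering differs."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        stain_names = meta["stain_names"]
        if expect_stain_names is not None and list(expect_stain_names) != stain_names:
            raise ValueError(
                f"checkpoint stain ordering {stain_names} differs from the run "
                f"configuration {list(expect_stain_names)}"
            )
        gen = Generator(GeneratorSpec(**meta["generator_spec"]))
        for i, p in enumerate(gen.params()):
            p.value = data[f"g{i}"].astype(np.float32)
        disc = None
        if meta["discriminator_spec"] is not None:
            disc = Discriminator(DiscriminatorSpec(**meta["discriminator_spec"]))
            for i, p in enumerate(disc.params()):
                p.value = data[f"d{i}"].astype(np.float32)
    return gen, stain_names, disc
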