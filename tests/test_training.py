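"""Loss operators against independent plug-in oracles; loop contracts."""

import numpy as np
import pytest

from microstain.network import DiscriminatorSpec, GeneratorSpec, build_discriminator, build_generator
from microstain.preprocessing import PatchPair
from microstain.training import (
    TrainingConfig,
    discriminator_loss,
    generator_loss,
    l1_distance,
    total_variation,
    train,
)


def tv_oracle(z):
    """Direct loop evaluation of the anisotropic TV sum."""
    z = np.atleast_3d(np.asarray(z, dtype=float))
    total = 0.0
    for c in range(z.shape[2]):
        for p in range(z.shape[0]):
            for q in range(z.shape[1]):
                if p + 1 < z.shape[0]:
                    total += abs(z[p + 1, q, c] - z[p, q, c])
                if q + 1 < z.shape[1]:
                    total += abs(z[p, q + 1, c] - z[p, q, c])
    return total


class TestTotalVariation:
    def test_constant_image_zero(self):
        assert total_variation(np.full((5, 7), 3.2)) == 0.0

    def test_two_by_two_example(self):
        assert total_variation(np.array([[0.0, 1.0], [0.0, 1.0]])) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(8, 8, 3))
        assert total_variation(z) == pytest.approx(tv_oracle(z), abs=1e-10)

    def test_nonnegative_and_shift_invariant(self, rng):
        z = rng.normal(size=(6, 6))
        assert total_variation(z) >= 0
        assert total_variation(z + 17.3) == pytest.approx(total_variation(z), abs=1e-9)


class TestL1Distance:
    def test_identical_images(self, rng):
        z = rng.normal(size=(5, 5, 3))
        assert l1_distance(z, z) == 0.0

    def test_ones_vs_zeros(self):
        assert l1_distance(np.ones((4, 6)), np.zeros((4, 6))) == 1.0

    def test_hand_example(self):
        assert l1_distance(np.array([[0.0, 1.0]]), np.array([[1.0, 1.0]])) == 0.5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_distance(np.zeros((2, 2)), np.zeros((3, 3)))


def _const_g(value):
    return lambda x, c: np.full((*x.shape[:2], 3), value)


def _const_d(score):
    return lambda img, c: score


class TestGeneratorLoss:
    def test_perfect_output_perfect_discriminator(self):
        z = np.full((8, 8, 3), 0.4)
        total, comps = generator_loss(z, z[..., :2], None, _const_g(0.4), _const_d(1.0))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_only_tv_survives(self, rng):
        z = rng.uniform(size=(8, 8, 3))
        G = lambda x, c: z
        total, comps = generator_loss(z, z[..., :2], None, G, _const_d(1.0), lam=0.02)
        assert total == pytest.approx(0.02 * total_variation(z), abs=1e-10)

    def test_plug_in_adversarial_value(self):
        z = np.full((8, 8, 3), 0.4)
        total, comps = generator_loss(
            z, z[..., :2], None, _const_g(0.4), _const_d(0.5), alpha=2000.0
        )
        assert total == pytest.approx(500.0, abs=1e-9)
        assert comps["adversarial"] == pytest.approx(2000.0 * 0.25)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_plug_in(self, seed):
        """Eq-by-eq oracle: L1 + lam*TV + alpha*(1-D)^2 with explicit loops."""
        rng = np.random.default_rng(seed)
        z = rng.uniform(size=(8, 8, 3))
        g_out = rng.uniform(size=(8, 8, 3))
        d_val = float(rng.uniform(0.1, 0.9))
        lam, alpha = 0.02, 2000.0
        total, comps = generator_loss(
            z, z[..., :2], None, lambda x, c: g_out, _const_d(d_val), lam, alpha
        )
        expected = (
            np.abs(z - g_out).mean() + lam * tv_oracle(g_out) + alpha * (1 - d_val) ** 2
        )
        assert total == pytest.approx(expected, abs=1e-10)
        assert total == pytest.approx(
            comps["l1"] + comps["tv"] + comps["adversarial"], abs=1e-12
        )


class TestDiscriminatorLoss:
    def test_perfect_discriminator_zero(self, rng):
        z = rng.uniform(size=(8, 8, 3))
        d = lambda img, c: 1.0 if img is z else 0.0
        assert discriminator_loss(z, z[..., :2], None, _const_g(0.3), d) == pytest.approx(0.0)

    def test_uninformative_discriminator(self, rng):
        z = rng.uniform(size=(8, 8, 3))
        loss = discriminator_loss(z, z[..., :2], None, _const_g(0.3), _const_d(0.5))
        assert loss == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_range_bound(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.uniform(size=(8, 8, 3))
        d = _const_d(float(rng.uniform(0.01, 0.99)))
        loss = discriminator_loss(z, z[..., :2], None, _const_g(0.3), d)
        assert 0.0 <= loss <= 2.0


def _toy_dataset(n=24, size=32, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ch = rng.normal(size=(size, size, 2)).astype(np.float32)
        # target correlated with input so there is something to learn
        t = np.stack([ch[..., 0], ch[..., 1], ch[..., 0] * 0.5], axis=-1)
        t = (t - t.min()) / (t.max() - t.min())
        out.append(PatchPair(channels=ch, target=t.astype(np.float32),
                             weights=np.eye(3)[i % 3]))
    return out


TOY_G = GeneratorSpec(levels=2, base_channels=4, n_stains=3)
TOY_D = DiscriminatorSpec(patch_size=32, stem_channels=4, blocks=2, n_stains=3)


class TestTrainLoop:
    def test_zero_steps_leaves_weights_unchanged(self):
        gen = build_generator(TOY_G, seed=0)
        disc = build_discriminator(TOY_D, seed=1)
        before = [p.value.copy() for p in gen.params()]
        cfg = TrainingConfig(total_discriminator_steps=0, seed=2)
        gen, history = train(_toy_dataset(), gen, disc, cfg)
        assert history == []
        for p, b in zip(gen.params(), before):
            assert np.array_equal(p.value, b)

    def test_component_decomposition_and_determinism(self):
        """Same seed -> bit-identical histories; components sum to total."""
        histories = []
        for _ in range(2):
            gen = build_generator(TOY_G, seed=0)
            disc = build_discriminator(TOY_D, seed=1)
            cfg = TrainingConfig(
                lr_generator=1e-3, lr_discriminator=2e-5,
                total_discriminator_steps=2, seed=7,
            )
            _, hist = train(_toy_dataset(), gen, disc, cfg)
            histories.append(hist)
        a, b = histories
        assert len(a) == 20
        for ra, rb in zip(a, b):
            assert ra.total == rb.total and ra.l1 == rb.l1
            assert ra.total == pytest.approx(ra.l1 + ra.tv + ra.adversarial, abs=1e-6)

    def test_l1_decreases_on_learnable_dataset(self):
        gen = build_generator(TOY_G, seed=0)
        disc = build_discriminator(TOY_D, seed=1)
        cfg = TrainingConfig(
            lr_generator=2e-3, lr_discriminator=4e-5,
            total_discriminator_steps=8, seed=3,
        )
        _, hist = train(_toy_dataset(n=32), gen, disc, cfg)
        assert hist[-1].l1 < 0.5 * hist[0].l1

    def test_empty_dataset_rejected(self):
        gen = build_generator(TOY_G, seed=0)
        disc = build_discriminator(TOY_D, seed=1)
        with pytest.raises(ValueError):
            train([], gen, disc, TrainingConfig(total_discriminator_steps=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(lr_generator=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(generator_steps_per_discriminator_step=0)
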