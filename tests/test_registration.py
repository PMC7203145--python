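"""Elastic pyramidal registration: block matching, warping, recovery."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from microstain.registration import (
    DisplacementField,
    apply_displacement,
    block_shift,
    coarse_register,
    elastic_pyramidal_register,
    refine_rigid,
)
from microstain.synthetic_data import generate_phantom, synthetic_warp


def smooth_texture(seed, shape=(64, 64)):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(size=shape), 2.0)


class TestBlockShift:
    def test_identical_blocks(self):
        ref = smooth_texture(0)
        m = block_shift(ref, ref)
        assert abs(m.shift[0]) < 0.1 and abs(m.shift[1]) < 0.1
        assert m.confidence == pytest.approx(1.0, abs=1e-6)

    def test_recovers_integer_shift(self):
        """Content translated by t yields shift t (wrap-free crops)."""
        canvas = smooth_texture(1, (96, 96))
        ref = canvas[16:80, 16:80]
        mov = canvas[16 - 3 : 80 - 3, 16 + 2 : 80 + 2]  # mov(p) = ref(p + (-3, 2))
        m = block_shift(ref, mov)
        assert abs(m.shift[0] - (-3)) < 0.5
        assert abs(m.shift[1] - 2) < 0.5

    def test_degenerate_block(self):
        ref = smooth_texture(2)
        m = block_shift(ref, np.zeros_like(ref))
        assert m.shift == (0.0, 0.0)
        assert m.confidence == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            block_shift(np.zeros((16, 16)), np.zeros((16, 8)))

    def test_too_small(self):
        with pytest.raises(ValueError):
            block_shift(np.zeros((4, 4)), np.zeros((4, 4)))


class TestApplyDisplacement:
    def test_zero_field_identity(self):
        img = smooth_texture(3)
        out = apply_displacement(img, DisplacementField(np.zeros((64, 64, 2))))
        assert np.allclose(out, img)

    def test_constant_integer_field_nearest(self):
        """Field (0, 1) moves content one column right: out(p) = img(p - f)."""
        img = np.arange(25, dtype=float).reshape(5, 5)
        field = np.zeros((5, 5, 2))
        field[..., 1] = 1.0
        out = apply_displacement(img, DisplacementField(field), "nearest")
        assert np.array_equal(out[:, 1:], img[:, :-1])
        assert np.array_equal(out[:, 0], img[:, 0])  # edge clamp

    def test_inverse_warp_symmetry(self):
        img = smooth_texture(4, (48, 48))
        f = np.zeros((48, 48, 2))
        f[..., 0] = 1.3
        f[..., 1] = -0.7
        back = apply_displacement(
            apply_displacement(img, DisplacementField(f)), DisplacementField(-f)
        )
        assert np.abs(back[4:-4, 4:-4] - img[4:-4, 4:-4]).max() < 0.05

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_displacement(np.zeros((8, 8)), DisplacementField(np.zeros((9, 9, 2))))


class TestElasticPyramid:
    def test_self_registration_is_zero(self):
        img = generate_phantom(0, 128, 128).channels[..., 1]
        f = elastic_pyramidal_register(img, img, min_block=16)
        assert f.magnitude().max() < 0.1

    def test_rigid_translation_recovered(self):
        canvas = generate_phantom(1, 320, 320).channels[..., 1]
        ref = canvas[24:280, 24:280]
        mov = canvas[24 + 4 : 280 + 4, 24 + 7 : 280 + 7]  # translated by (4, 7)
        f = elastic_pyramidal_register(ref, mov, min_block=32)
        err = np.sqrt(((f.shifts - np.array([4.0, 7.0])) ** 2).sum(-1))
        assert err.mean() < 0.5

    def test_smooth_warp_recovered_and_correlation_improves(self):
        img = generate_phantom(2, 256, 256).channels[..., 1]
        warped, gt = synthetic_warp(img, 5, amplitude=4.0)
        f = elastic_pyramidal_register(img, warped, min_block=32)
        interior = (slice(24, -24), slice(24, -24))
        epe = np.sqrt(((f.shifts - gt) ** 2).sum(-1))[interior].mean()
        assert epe < 1.5

        def ncc(a, b):
            a = (a - a.mean()) / a.std()
            b = (b - b.mean()) / b.std()
            return float((a * b).mean())

        assert ncc(img, apply_displacement(warped, f)) > ncc(img, warped)

    def test_error_non_increasing_across_levels(self):
        """More pyramid levels never hurt on a synthetic smooth warp."""
        img = generate_phantom(3, 256, 256).channels[..., 1]
        warped, gt = synthetic_warp(img, 9, amplitude=5.0)
        errs = []
        for min_block in (52, 32, 16):  # 1, 2, 3 levels for a 256-px image
            f = elastic_pyramidal_register(img, warped, min_block=min_block)
            errs.append(np.sqrt(((f.shifts - gt) ** 2).sum(-1))[24:-24, 24:-24].mean())
        assert errs[1] <= errs[0] + 0.05
        assert errs[2] <= errs[1] + 0.05

    def test_translation_equivariance(self):
        canvas = generate_phantom(4, 400, 400).channels[..., 1]
        warped_canvas, _ = synthetic_warp(canvas, 6, amplitude=3.0)
        ref_a, mov_a = canvas[40:296, 40:296], warped_canvas[40:296, 40:296]
        ref_b, mov_b = canvas[56:312, 56:312], warped_canvas[56:312, 56:312]
        fa = elastic_pyramidal_register(ref_a, mov_a, min_block=32)
        fb = elastic_pyramidal_register(ref_b, mov_b, min_block=32)
        # compare the overlapping interiors in absolute coordinates
        a = fa.shifts[40:216, 40:216]
        b = fb.shifts[24:200, 24:200]
        assert np.abs(a - b).mean() < 0.2

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            elastic_pyramidal_register(np.zeros((64, 64)), np.zeros((32, 32)))

    def test_tiny_image_falls_back_to_global_shift(self):
        canvas = smooth_texture(7, (48, 48))
        ref = canvas[4:36, 4:36]
        mov = canvas[6:38, 5:37]  # translated by (2, 1)
        f = elastic_pyramidal_register(ref, mov)  # 32/5 < 8 -> global fallback
        assert np.allclose(f.shifts[..., 0], f.shifts[0, 0, 0])
        assert abs(f.shifts[0, 0, 0] - 2) < 0.5
        assert abs(f.shifts[0, 0, 1] - 1) < 0.5


class TestCoarseRegister:
    def test_embedded_inverted_dapi_found(self):
        rng = np.random.default_rng(0)
        dapi = generate_phantom(8, 128, 128).channels[..., 0]
        canvas = rng.normal(0.5, 0.05, (360, 300))
        inv = dapi.max() - dapi
        canvas[120 : 120 + 128, 80 : 80 + 128] = inv
        offset, crop = coarse_register(canvas, dapi)
        assert abs(offset[0] - 120) <= 1 and abs(offset[1] - 80) <= 1
        assert crop.shape == dapi.shape

    def test_zero_offset(self):
        dapi = generate_phantom(9, 96, 96).channels[..., 0]
        canvas = dapi.max() - dapi
        offset, _ = coarse_register(canvas, dapi)
        assert offset == (0, 0)

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            coarse_register(np.ones((64, 64)), np.ones((32, 32)))


class TestRefineRigid:
    def test_prealigned_identity(self):
        img = generate_phantom(10, 96, 96).channels[..., 0]
        ang, (ty, tx) = refine_rigid(img, img)
        assert abs(ang) < 0.2 and abs(ty) < 1 and abs(tx) < 1

    def test_known_rotation_recovered(self):
        img = generate_phantom(11, 128, 128).channels[..., 0]
        rotated = ndimage.rotate(img, -2.0, reshape=False, order=1, mode="nearest")
        ang, _ = refine_rigid(img, rotated)
        assert ang == pytest.approx(2.0, abs=0.2)

    def test_unrelated_images_warn_identity(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(64, 64))
        b = rng.uniform(size=(64, 64))
        with warnings.catch_warnings(record=True):
            warnings.simplefilter("always")
            ang, (ty, tx) = refine_rigid(a, np.full_like(b, 0.5))
        assert (ang, ty, tx) == (0.0, 0.0, 0.0)
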