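"""Apply a trained model: single stains, blends, micro-structured staining.

A trained generator maps a two-channel autofluorescence stack plus a
digital staining matrix to a stained image in YCbCr; export converts to
8-bit RGB (BT.601 full range).  Whole slides larger than one network tile
are processed with overlapping tiles whose overlap bands are blended by
linear feathering, so uniform-condition tiled output agrees with a
single-pass run away from tile seams.
"""

from __future__ import annotations

import numpy as np

from .color import to_uint8, ycbcr_to_rgb
from .network import Generator
from .staining_matrix import DigitalStainingMatrix, RoiSpec, blend_matrix, roi_matrix

__all__ = ["stain_patch", "stain_slide", "blend_series", "micro_structured_stain"]


def _forward_ycbcr(
    model: Generator, af: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    x = np.concatenate([af, weights], axis=2).astype(np.float32)[None]
    return model.forward(x)[0].astype(np.float64)


def stain_patch(
    model: Generator,
    af_patch: np.ndarray,
    dsm: DigitalStainingMatrix,
    as_uint8: bool = True,
) -> np.ndarray:
    """Virtually stain one patch under a validated staining matrix.

    ``af_patch`` is (H, W, 2) with H, W divisible by 2^levels; the output is
    (H, W, 3) 8-bit RGB (or float YCbCr in [0, 1] network units with
    ``as_uint8=False``).  Deterministic given weights and input.
    """
    af_patch = np.asarray(af_patch, dtype=np.float64)
    if af_patch.ndim != 3 or af_patch.shape[2] != model.spec.in_channels:
        raise ValueError(
            f"expected (H, W, {model.spec.in_channels}) autofluorescence stack, "
            f"got {af_patch.shape}"
        )
    if dsm.weights.shape[:2] != af_patch.shape[:2]:
        raise ValueError(
            f"staining matrix {dsm.weights.shape[:2]} does not match patch "
            f"{af_patch.shape[:2]}"
        )
    dsm.check()
    out = _forward_ycbcr(model, af_patch, dsm.weights)
    if not np.isfinite(out).all():
        raise FloatingPointError("generator produced non-finite output")
    if not as_uint8:
        return out
    return to_uint8(ycbcr_to_rgb(out * 255.0))


def _feather_profile(n: int, overlap_lo: bool, overlap_hi: bool, overlap: int) -> np.ndarray:
    w = np.ones(n)
    if overlap > 0:
        ramp = (np.arange(1, overlap + 1)) / (overlap + 1)
        if overlap_lo:
            w[:overlap] = ramp
        if overlap_hi:
            w[-overlap:] = ramp[::-1]
    return w


def stain_slide(
    model: Generator,
    af_slide: np.ndarray,
    dsm: DigitalStainingMatrix,
    tile: int = 256,
    overlap: int = 32,
    as_uint8: bool = True,
) -> np.ndarray:
    """Tiled whole-slide inference with linear feathering in overlap bands.

    The slide is covered by ``tile x tile`` windows advancing by
    ``tile - overlap``; each window is stained independently and the results
    are accumulated with separable linear ramp weights over the overlap
    bands.  Output dimensions equal the input dimensions.  A slide no larger
    than one tile falls back to a single :func:`stain_patch` pass.
    """
    af_slide = np.asarray(af_slide, dtype=np.float64)
    h, w = af_slide.shape[:2]
    dsm.check()
    if dsm.weights.shape[:2] != (h, w):
        raise ValueError("staining matrix shape does not match the slide")
    div = 2**model.spec.levels
    if tile % div:
        raise ValueError(f"tile size {tile} not divisible by 2^{model.spec.levels}")
    if overlap < 0 or overlap >= tile:
        raise ValueError("overlap must be in [0, tile)")
    if h <= tile and w <= tile:
        if h % div or w % div:
            raise ValueError(
                f"slide size {h}x{w} must be divisible by 2^{model.spec.levels}"
            )
        return stain_patch(model, af_slide, dsm, as_uint8=as_uint8)

    step = tile - overlap
    acc = np.zeros((h, w, 3))
    norm = np.zeros((h, w, 1))
    rows = sorted({min(r, h - tile) for r in range(0, h - tile + step, step)})
    cols = sorted({min(c, w - tile) for c in range(0, w - tile + step, step)})
    for r in rows:
        for c in cols:
            sl = (slice(r, r + tile), slice(c, c + tile))
            sub = DigitalStainingMatrix(dsm.weights[sl], dsm.stain_names)
            out = _forward_ycbcr(model, af_slide[sl], sub.weights)
            wr = _feather_profile(tile, r > 0, r + tile < h, overlap)
            wc = _feather_profile(tile, c > 0, c + tile < w, overlap)
            wgt = (wr[:, None] * wc[None, :])[..., None]
            acc[sl] += out * wgt
            norm[sl] += wgt
    out = acc / np.maximum(norm, 1e-12)
    if not as_uint8:
        return out
    return to_uint8(ycbcr_to_rgb(out * 255.0))


def blend_series(
    model: Generator,
    af_image: np.ndarray,
    stain_a: int,
    stain_b: int,
    ratios: list[float],
    as_uint8: bool = True,
) -> list[np.ndarray]:
    """Sweep blend ratios between two stains (ratio r: r*e_a + (1-r)*e_b)."""
    n = model.spec.n_stains
    h, w = np.asarray(af_image).shape[:2]
    out = []
    for r in ratios:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"blend ratio {r} outside [0, 1]")
        weights = np.zeros(n)
        weights[stain_a - 1] += r
        weights[stain_b - 1] += 1.0 - r
        dsm = blend_matrix(weights, h, w)
        out.append(stain_slide(model, af_image, dsm, as_uint8=as_uint8))
    return out


def micro_structured_stain(
    model: Generator,
    af_image: np.ndarray,
    roi_spec: RoiSpec,
    tile: int = 256,
    overlap: int = 32,
    as_uint8: bool = True,
) -> np.ndarray:
    """Stain user-defined regions with different stains in one pass.

    Builds the per-pixel staining matrix from the ROI polygons and runs
    (tiled) inference; the interior of each ROI renders as the
    corresponding uniform condition would, with mixing confined to a
    receptive-field-wide band at ROI boundaries.
    """
    h, w = np.asarray(af_image).shape[:2]
    dsm = roi_matrix(roi_spec, h, w)
    return stain_slide(model, af_image, dsm, tile=tile, overlap=overlap, as_uint8=as_uint8)
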