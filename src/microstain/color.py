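"""RGB <-> YCbCr conversion (ITU-R BT.601, full range).

The generator is trained to emit bright-field images in YCbCr — the colour
space the conditional discriminator consumes — and conversion to RGB happens
only at export time.  The full-range (JPEG) BT.601 matrix is used throughout
the package so that metric computations and inference exports agree exactly:

    Y  =  0.299 R + 0.587 G + 0.114 B
    Cb = 128 - 0.168736 R - 0.331264 G + 0.5 B
    Cr = 128 + 0.5 R - 0.418688 G - 0.081312 B

All functions operate on float arrays scaled 0..255 with channels last.
"""

from __future__ import annotations

import numpy as np

_RGB2YCBCR = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_OFFSET = np.array([0.0, 128.0, 128.0])
_YCBCR2RGB = np.linalg.inv(_RGB2YCBCR)


def rgb_to_ycbcr(rgb: np.ndarray) -> np.ndarray:
    """Convert an (..., 3) RGB array (0..255) to YCbCr (0..255), float."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected 3 colour channels, got shape {rgb.shape}")
    return rgb @ _RGB2YCBCR.T + _OFFSET


def ycbcr_to_rgb(ycbcr: np.ndarray) -> np.ndarray:
    """Convert an (..., 3) YCbCr array (0..255) to RGB (0..255), float.

    Output is not clipped; callers exporting 8-bit images should use
    :func:`to_uint8`.
    """
    ycbcr = np.asarray(ycbcr, dtype=np.float64)
    if ycbcr.shape[-1] != 3:
        raise ValueError(f"expected 3 colour channels, got shape {ycbcr.shape}")
    return (ycbcr - _OFFSET) @ _YCBCR2RGB.T


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Clip to [0, 255], round half away from zero handled by np.rint, cast."""
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)
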