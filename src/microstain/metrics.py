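"""Evaluation metrics: whole-patch SSIM and YCbCr percentage differences.

The structural similarity index between two images a and b is computed from
whole-patch statistics,

    SSIM(a, b) = (2 mu_a mu_b + C1)(2 sigma_ab + C2)
                 / ((mu_a^2 + mu_b^2 + C1)(sigma_a^2 + sigma_b^2 + C2)),

with population means, variances and cross-covariance over the whole patch
and the usual stabilization constants C1 = (0.01 L)^2, C2 = (0.03 L)^2 for
dynamic range L = 255.  A sliding-window mean-SSIM variant is available
behind a flag; the whole-patch statistic is the default.

Colour agreement between an output and a reference is summarized per YCbCr
channel as the mean absolute difference expressed as a percentage of the
full 8-bit channel range (an alternative normalization by the reference
channel mean is available).  Reports aggregate both metrics over a grid of
non-overlapping evaluation patches (1224 x 1224 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import rgb_to_ycbcr

EVAL_PATCH = 1224


@dataclass(frozen=True)
class SsimParams:
    """Stabilization constants for SSIM; defaults follow dynamic range L."""

    dynamic_range: float = 255.0
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def ssim_global(
    a: np.ndarray, b: np.ndarray, params: SsimParams = SsimParams()
) -> float:
    """Whole-patch SSIM in [-1, 1]; multi-channel images average per channel."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.ndim == 3:
        return float(
            np.mean([ssim_global(a[..., c], b[..., c], params) for c in range(a.shape[2])])
        )
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    c1, c2 = params.c1, params.c2
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def ssim_windowed(
    a: np.ndarray, b: np.ndarray, params: SsimParams = SsimParams(), win_size: int = 7
) -> float:
    """Sliding-window mean SSIM (offered for comparison; not the default)."""
    from skimage.metrics import structural_similarity

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    kwargs = dict(
        data_range=params.dynamic_range, K1=params.k1, K2=params.k2, win_size=win_size
    )
    if a.ndim == 3:
        kwargs["channel_axis"] = -1
    return float(structural_similarity(a, b, **kwargs))


def ycbcr_percent_diff(
    a: np.ndarray, b: np.ndarray, normalization: str = "range"
) -> tuple[float, float, float]:
    """Mean absolute YCbCr differences between two RGB images, in percent.

    With ``normalization="range"`` (default) each channel's mean absolute
    difference is divided by the full 8-bit range (255); with
    ``normalization="mean"`` it is divided by the reference (b) channel
    mean.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("expected (H, W, 3) RGB images")
    ya, yb = rgb_to_ycbcr(a), rgb_to_ycbcr(b)
    mad = np.abs(ya - yb).mean(axis=(0, 1))
    if normalization == "range":
        denom = np.full(3, 255.0)
    elif normalization == "mean":
        denom = yb.mean(axis=(0, 1))
    else:
        raise ValueError("normalization must be 'range' or 'mean'")
    pct = 100.0 * mad / denom
    return float(pct[0]), float(pct[1]), float(pct[2])


@dataclass
class MetricsReport:
    """Per-patch metric rows plus per-comparison aggregates."""

    ssim: np.ndarray  # (n_patches,)
    y_pct: np.ndarray
    cb_pct: np.ndarray
    cr_pct: np.ndarray

    @property
    def n_patches(self) -> int:
        return len(self.ssim)

    def summary(self) -> dict[str, tuple[float, float]]:
        """(mean, standard deviation) per metric, mirroring the table layout."""
        out = {}
        for name in ("ssim", "y_pct", "cb_pct", "cr_pct"):
            vals = getattr(self, name)
            out[name] = (float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else 0.0))
        return out

    def to_rows(self) -> list[dict]:
        return [
            {
                "patch": i,
                "ssim": float(self.ssim[i]),
                "y_pct": float(self.y_pct[i]),
                "cb_pct": float(self.cb_pct[i]),
                "cr_pct": float(self.cr_pct[i]),
            }
            for i in range(self.n_patches)
        ]


def evaluate(
    outputs: list[np.ndarray] | np.ndarray,
    references: list[np.ndarray] | np.ndarray,
    patch: int = EVAL_PATCH,
    params: SsimParams = SsimParams(),
) -> MetricsReport:
    """Tile image pairs into non-overlapping patches and aggregate metrics.

    ``outputs`` and ``references`` are paired, co-registered RGB images (or
    single images).  Each pair is tiled into ``patch x patch`` blocks
    (partial edge blocks discarded); SSIM is computed per block on the RGB
    channels (averaged) and colour differences per block in YCbCr.
    """
    if isinstance(outputs, np.ndarray):
        outputs = [outputs]
    if isinstance(references, np.ndarray):
        references = [references]
    if len(outputs) != len(references):
        raise ValueError("outputs and references must pair up")
    ssim_rows, y_rows, cb_rows, cr_rows = [], [], [], []
    for out, ref in zip(outputs, references):
        out = np.asarray(out)
        ref = np.asarray(ref)
        if out.shape != ref.shape:
            raise ValueError(f"pair shapes differ: {out.shape} vs {ref.shape}")
        h, w = out.shape[:2]
        for r in range(0, h - patch + 1, patch):
            for c in range(0, w - patch + 1, patch):
                sl = (slice(r, r + patch), slice(c, c + patch))
                ssim_rows.append(ssim_global(out[sl], ref[sl], params))
                y, cb, cr = ycbcr_percent_diff(out[sl], ref[sl])
                y_rows.append(y)
                cb_rows.append(cb)
                cr_rows.append(cr)
    if not ssim_rows:
        raise ValueError(
            f"no complete {patch}x{patch} blocks fit the images; use a smaller patch size"
        )
    return MetricsReport(
        ssim=np.asarray(ssim_rows),
        y_pct=np.asarray(y_rows),
        cb_pct=np.asarray(cb_rows),
        cr_pct=np.asarray(cr_rows),
    )
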