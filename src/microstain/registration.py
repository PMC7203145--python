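"""Elastic pyramidal co-registration and coarse cross-correlation alignment.

Two autofluorescence channels captured through different filter cubes are
not perfectly aligned, particularly toward the edges of each field of view.
The elastic registration algorithm matches local features hierarchically:
the image is divided into a grid of blocks (5 x 5 to start), block-wise
normalized cross-correlations locate each block's translation, the per-block
translations are interpolated into a dense translation map by a weighted
average, and the moving image is warped; the procedure repeats with blocks
of half the size until the block size would drop below a minimum (100 px by
default).

Sign convention (fixed throughout the package): the returned
:class:`DisplacementField` ``f`` warps the *moving* image onto the
reference via ``output(p) = moving(p - f(p))``; a moving image that is the
reference translated by ``t`` (``moving(p) = reference(p + t)``) yields
``f ~ t`` everywhere.

Bright-field images of the histochemically stained tissue live in a
different modality; they are coarsely located by sliding a contrast-reversed
DAPI image over the bright-field mosaic (normalized cross-correlation) and
can then be refined with a small rigid mutual-information search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import match_template
from skimage.transform import resize

__all__ = [
    "BlockMatch",
    "DisplacementField",
    "apply_displacement",
    "block_shift",
    "coarse_register",
    "elastic_pyramidal_register",
    "refine_rigid",
]

MIN_BLOCK_SIDE = 8
CONFIDENCE_FLOOR = 0.2  # blocks below this inherit their neighbours' shift


@dataclass
class DisplacementField:
    """Dense per-pixel (row-shift, col-shift) map, shape (H, W, 2)."""

    shifts: np.ndarray

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.shifts.ndim != 3 or self.shifts.shape[2] != 2:
            raise ValueError(f"shifts must be (H, W, 2), got {self.shifts.shape}")
        if not np.isfinite(self.shifts).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.shifts.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.shifts**2).sum(axis=-1))


@dataclass
class BlockMatch:
    """Result of matching one block: center, shift and NCC confidence."""

    center: tuple[float, float]
    shift: tuple[float, float]
    confidence: float


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if abs(denom) < 1e-12:
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def block_shift(reference_block: np.ndarray, moving_block: np.ndarray) -> BlockMatch:
    """Locate the moving block's content within the reference block.

    The central region of the moving block (a margin of a quarter block is
    trimmed on each side) is slid over the full reference block by
    normalized cross-correlation, so shifts of up to a quarter block are
    found with properly normalized correlations at every candidate offset.
    The shift is the offset of the NCC peak from zero displacement, refined
    to sub-pixel precision by 1-D parabolic fits along each axis;
    confidence is the peak NCC value.  A constant block (zero variance) is
    a degenerate signal: shift (0, 0), confidence 0.  Equal correlation
    peaks break ties toward the smallest row, then column.
    """
    ref = np.asarray(reference_block, dtype=np.float64)
    mov = np.asarray(moving_block, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError(f"block shapes differ: {ref.shape} vs {mov.shape}")
    if min(ref.shape) < MIN_BLOCK_SIDE:
        raise ValueError(f"blocks must be at least {MIN_BLOCK_SIDE} px per side")
    h, w = ref.shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    my, mx = h // 4, w // 4
    template = mov[my : h - my, mx : w - mx]
    if ref.std() < 1e-12 or template.std() < 1e-12:
        return BlockMatch(center=center, shift=(0.0, 0.0), confidence=0.0)
    ncc = match_template(ref, template)  # valid mode: shape (2*my+1, 2*mx+1)
    peak = np.unravel_index(int(np.argmax(ncc)), ncc.shape)  # ties -> lowest row, col
    conf = float(ncc[peak])
    # template cut at (my, mx) matching at (my, mx) means zero displacement
    dy = float(peak[0] - my)
    dx = float(peak[1] - mx)
    if 0 < peak[0] < ncc.shape[0] - 1:
        dy += _parabolic_offset(ncc[peak[0] - 1, peak[1]], conf, ncc[peak[0] + 1, peak[1]])
    if 0 < peak[1] < ncc.shape[1] - 1:
        dx += _parabolic_offset(ncc[peak[0], peak[1] - 1], conf, ncc[peak[0], peak[1] + 1])
    return BlockMatch(center=center, shift=(dy, dx), confidence=conf)


def apply_displacement(
    image: np.ndarray,
    field: DisplacementField | np.ndarray,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Warp ``image`` by a displacement field: out(p) = image(p - field(p)).

    Out-of-bounds samples take the nearest edge value.  ``interpolation`` is
    ``"bilinear"`` or ``"nearest"``.
    """
    shifts = field.shifts if isinstance(field, DisplacementField) else np.asarray(field)
    image = np.asarray(image, dtype=np.float64)
    if shifts.shape[:2] != image.shape[:2]:
        raise ValueError(
            f"field shape {shifts.shape[:2]} does not match image {image.shape[:2]}"
        )
    orders = {"nearest": 0, "bilinear": 1}
    if interpolation not in orders:
        raise ValueError(f"interpolation must be one of {sorted(orders)}")
    rows, cols = np.mgrid[0 : image.shape[0], 0 : image.shape[1]].astype(np.float64)
    coords = [rows - shifts[..., 0], cols - shifts[..., 1]]
    if image.ndim == 2:
        return ndimage.map_coordinates(image, coords, order=orders[interpolation], mode="nearest")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            image[..., c], coords, order=orders[interpolation], mode="nearest"
        )
    return out


def _interpolate_shifts(
    centers: np.ndarray, shifts: np.ndarray, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Gaussian-weighted inverse-distance interpolation of block shifts.

    Evaluated on a stride-4 lattice and bilinearly resized to full
    resolution (the field is smooth by construction, so this loses nothing
    measurable and keeps whole-slide fields cheap).
    """
    h, w = shape
    step = 4 if min(h, w) >= 64 else 1
    gy = np.arange(0, h, step, dtype=np.float64)
    gx = np.arange(0, w, step, dtype=np.float64)
    yy, xx = np.meshgrid(gy, gx, indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)  # (P, 2)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1)  # (P, B)
    wgt = np.exp(-d2 / (2.0 * sigma**2))
    wgt_sum = wgt.sum(axis=1, keepdims=True)
    wgt = np.where(wgt_sum > 1e-12, wgt / np.maximum(wgt_sum, 1e-300), 1.0 / len(centers))
    dense = wgt @ shifts  # (P, 2)
    dense = dense.reshape(len(gy), len(gx), 2)
    if step == 1:
        return dense
    return resize(dense, (h, w, 2), order=1, mode="edge", anti_aliasing=False)


def elastic_pyramidal_register(
    reference: np.ndarray,
    moving: np.ndarray,
    start_grid: int = 5,
    min_block: int = 100,
) -> DisplacementField:
    """Hierarchical block-matching registration of two same-shape images.

    Level 0 splits the image into ``start_grid x start_grid`` blocks; each
    level matches blocks between the reference and the currently warped
    moving image, interpolates the per-block shifts into a dense map
    (Gaussian falloff, sigma = half the block spacing), composes it with the
    running field, and re-warps.  Block size halves per level and iteration
    stops before it would drop below ``min_block``.  Images smaller than one
    matchable block fall back to a single global shift.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError(f"image shapes differ: {ref.shape} vs {mov.shape}")
    if ref.ndim != 2:
        raise ValueError("elastic registration operates on 2-D images")
    h, w = ref.shape
    field = np.zeros((h, w, 2))

    bh = int(np.ceil(h / start_grid))
    bw = int(np.ceil(w / start_grid))
    if min(bh, bw) < MIN_BLOCK_SIDE:
        match = block_shift(ref, mov)
        field[...] = match.shift
        return DisplacementField(field)

    warped = mov
    level = 0
    while level == 0 or min(bh, bw) >= min_block:
        ny = max(1, int(round(h / bh)))
        nx = max(1, int(round(w / bw)))
        centers, shifts, confs = [], [], []
        for iy in range(ny):
            r0 = int(round(iy * h / ny))
            r1 = int(round((iy + 1) * h / ny))
            for ix in range(nx):
                c0 = int(round(ix * w / nx))
                c1 = int(round((ix + 1) * w / nx))
                m = block_shift(ref[r0:r1, c0:c1], warped[r0:r1, c0:c1])
                centers.append(((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0))
                shifts.append(m.shift)
                confs.append(m.confidence)
        centers = np.asarray(centers)
        shifts = np.asarray(shifts)
        confs = np.asarray(confs)
        good = confs >= CONFIDENCE_FLOOR
        if good.any():
            sigma = 0.5 * max(h / ny, w / nx)
            increment = _interpolate_shifts(centers[good], shifts[good], (h, w), sigma)
            field += increment
            warped = apply_displacement(mov, DisplacementField(field))
        bh //= 2
        bw //= 2
        level += 1
        if min(bh, bw) < MIN_BLOCK_SIDE:
            break
    return DisplacementField(field)


def coarse_register(
    brightfield_gray: np.ndarray, dapi: np.ndarray
) -> tuple[tuple[int, int], np.ndarray]:
    """Locate the DAPI field of view inside a larger bright-field image.

    The DAPI image is contrast-reversed (max - pixel) and slid over the
    bright-field image by normalized cross-correlation; returns the
    top-left offset of the best match and the matching crop.  Ties break
    toward the smallest row, then column.
    """
    bf = np.asarray(brightfield_gray, dtype=np.float64)
    dp = np.asarray(dapi, dtype=np.float64)
    if bf.shape[0] < dp.shape[0] or bf.shape[1] < dp.shape[1]:
        raise ValueError("bright-field image must be at least as large as the DAPI image")
    if bf.std() < 1e-12 or dp.std() < 1e-12:
        raise ValueError("degenerate (zero-variance) input to coarse registration")
    inverted = dp.max() - dp
    ncc = match_template(bf, inverted)  # valid-mode: (H-h+1, W-w+1)
    peak = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    r, c = int(peak[0]), int(peak[1])
    crop = bf[r : r + dp.shape[0], c : c + dp.shape[1]]
    return (r, c), crop


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def _rigid_transform(image: np.ndarray, angle_deg: float, ty: float, tx: float) -> np.ndarray:
    out = ndimage.rotate(image, angle_deg, reshape=False, order=1, mode="nearest")
    return ndimage.shift(out, (ty, tx), order=1, mode="nearest")


def refine_rigid(
    reference: np.ndarray,
    moving: np.ndarray,
    max_angle: float = 5.0,
    max_shift: float = 20.0,
) -> tuple[float, tuple[float, float]]:
    """Small rigid refinement between modalities by mutual information.

    Searches rotation within +/- ``max_angle`` degrees and translation
    within +/- ``max_shift`` px (coarse grid then Powell polish) for the
    transform of ``moving`` that maximizes mutual information with
    ``reference``.  Returns ``(angle_deg, (ty, tx))``; when no transform
    improves on identity, returns the identity with a warning.
    """
    ref = np.asarray(reference, dtype=np.float64)
    mov = np.asarray(moving, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError("refine_rigid expects same-shape images")
    if ref.std() < 1e-9 or mov.std() < 1e-9:
        warnings.warn(
            "rigid refinement got a (near-)constant image; returning identity",
            stacklevel=2,
        )
        return 0.0, (0.0, 0.0)

    def neg_mi(params):
        ang, ty, tx = params
        if abs(ang) > max_angle or abs(ty) > max_shift or abs(tx) > max_shift:
            return 0.0
        return -_mutual_information(ref, _rigid_transform(mov, ang, ty, tx))

    base = -neg_mi((0.0, 0.0, 0.0))
    best = (0.0, 0.0, 0.0)
    best_mi = base
    for ang in np.linspace(-max_angle, max_angle, 11):
        for ty in np.linspace(-max_shift, max_shift, 5):
            for tx in np.linspace(-max_shift, max_shift, 5):
                mi = -neg_mi((ang, ty, tx))
                if mi > best_mi:
                    best_mi = mi
                    best = (float(ang), float(ty), float(tx))
    res = optimize.minimize(
        neg_mi, best, method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 200},
    )
    if -res.fun > base + 1e-6:
        ang, ty, tx = res.x
        return float(ang), (float(ty), float(tx))
    if best_mi > base + 1e-6:
        ang, ty, tx = best
        return float(ang), (float(ty), float(tx))
    warnings.warn("rigid refinement found no transform improving mutual information; "
                  "returning identity", stacklevel=2)
    return 0.0, (0.0, 0.0)
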