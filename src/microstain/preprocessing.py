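"""Whole-slide normalization and patch dataset construction.

Whole-slide autofluorescence channels are standardized against tissue
statistics only — the mean and standard deviation are computed over a
tissue mask so that empty background does not bias them — and the
registered slide pairs are cut into overlapping 256 x 256 patches (with a
configurable stride and seeded jitter) for training, keeping only patches
that are mostly tissue.  Patches are augmented with the eight dihedral
transforms (four rotations times an optional flip) applied identically to
the input stack, the target and the per-pixel staining matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

PATCH_SIZE = 256
DEFAULT_STRIDE = 128  # 50% overlap
TISSUE_FRACTION = 0.5


class EmptyMaskError(ValueError):
    """The slide contains no detectable tissue."""


class DegenerateSlideError(ValueError):
    """Masked pixel values are constant; normalization is undefined."""


@dataclass
class SlidePair:
    """A registered (autofluorescence stack, stained target) slide.

    ``target`` is the stained image in YCbCr scaled to [0, 1]; ``weights``
    is either a length-N stain weight vector (uniform condition) or a full
    per-pixel staining matrix.
    """

    channels: np.ndarray  # (H, W, 2) float
    target: np.ndarray  # (H, W, 3) float
    mask: np.ndarray  # (H, W) bool
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.channels.shape[:2] != self.target.shape[:2]:
            raise ValueError("channel and target shapes disagree")
        if self.mask.shape != self.channels.shape[:2]:
            raise ValueError("mask shape disagrees with channels")


@dataclass
class PatchPair:
    """One aligned training unit cut from a slide."""

    channels: np.ndarray  # (size, size, 2)
    target: np.ndarray  # (size, size, 3)
    weights: np.ndarray  # (n_stains,) or (size, size, n_stains)
    row: int = 0
    col: int = 0
    slide_id: int = -1


def tissue_mask(channel: np.ndarray, min_component: int = 64) -> np.ndarray:
    """Foreground mask: Otsu threshold after 3x3 median smoothing.

    Connected components smaller than ``min_component`` pixels are dropped.
    Raises :class:`EmptyMaskError` for an (effectively) constant image.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("empty image")
    smoothed = ndimage.median_filter(channel, size=3)
    if smoothed.max() - smoothed.min() < 1e-12:
        raise EmptyMaskError("image is constant; no tissue/background contrast")
    mask = smoothed > threshold_otsu(smoothed)
    labels = cc_label(mask)
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = sizes >= min(min_component, sizes.max())
        mask = keep[labels]
    if not mask.any():
        raise EmptyMaskError("no foreground pixels above the automatic threshold")
    return mask


def normalize_slide(channel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize a channel by its tissue statistics.

    output = (channel - mean over mask) / (std over mask), applied to every
    pixel.  Idempotent: reapplying to an already-normalized channel changes
    nothing (masked mean 0, std 1).
    """
    channel = np.asarray(channel, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot normalize with an empty tissue mask")
    vals = channel[mask]
    std = vals.std()
    if std < 1e-12:
        raise DegenerateSlideError("tissue pixels are constant; zero standard deviation")
    return (channel - vals.mean()) / std


def extract_patches(
    pair: SlidePair,
    size: int = PATCH_SIZE,
    stride: int = DEFAULT_STRIDE,
    jitter: int = 0,
    min_tissue: float = TISSUE_FRACTION,
    seed: int = 0,
    slide_id: int = -1,
) -> list[PatchPair]:
    """Cut a slide into overlapping patches on a stride grid.

    Optional seeded ``jitter`` perturbs each grid position by up to +/-
    ``jitter`` pixels (clipped to bounds); patches whose tissue fraction is
    below ``min_tissue`` are discarded.  No patch ever crosses the slide
    bounds.
    """
    h, w = pair.channels.shape[:2]
    if h < size or w < size:
        raise ValueError(
            f"slide ({h}x{w}) is smaller than the patch size {size}; pad the slide first"
        )
    if stride >= size:
        raise ValueError("stride must be smaller than the patch size (overlapping patches)")
    rng = np.random.default_rng(seed)
    per_pixel = pair.weights.ndim == 3
    out: list[PatchPair] = []
    for r in range(0, h - size + 1, stride):
        for c in range(0, w - size + 1, stride):
            if jitter:
                r_j = int(np.clip(r + rng.integers(-jitter, jitter + 1), 0, h - size))
                c_j = int(np.clip(c + rng.integers(-jitter, jitter + 1), 0, w - size))
            else:
                r_j, c_j = r, c
            sl = (slice(r_j, r_j + size), slice(c_j, c_j + size))
            if pair.mask[sl].mean() < min_tissue:
                continue
            out.append(
                PatchPair(
                    channels=pair.channels[sl].copy(),
                    target=pair.target[sl].copy(),
                    weights=pair.weights[sl].copy() if per_pixel else pair.weights.copy(),
                    row=r_j,
                    col=c_j,
                    slide_id=slide_id,
                )
            )
    return out


def save_patch_dataset(directory, patches: list[PatchPair], split: str = "train") -> None:
    """Persist patches as per-patch 32-bit TIFF stacks plus a manifest TSV.

    Each patch becomes ``patch<idx>.tif`` holding the concatenated
    (channels | target) planes; per-pixel staining matrices are stored as
    additional planes, uniform weight vectors inline in the manifest.
    """
    from pathlib import Path

    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patches):
        planes = [p.channels, p.target]
        per_pixel = p.weights.ndim == 3
        if per_pixel:
            planes.append(p.weights)
        stack = np.concatenate(planes, axis=2).astype(np.float32)
        name = f"patch{i:05d}.tif"
        tifffile.imwrite(directory / name, np.moveaxis(stack, -1, 0))
        rows.append(
            {
                "patch_id": i,
                "file": name,
                "slide_id": p.slide_id,
                "row": p.row,
                "col": p.col,
                "split": split,
                "n_stains": p.weights.shape[-1],
                "weights": "per-pixel" if per_pixel else ",".join(
                    f"{w:.6f}" for w in p.weights
                ),
            }
        )
    from .io import write_manifest

    write_manifest(directory / "manifest.tsv", rows)


def load_patch_dataset(directory) -> list[PatchPair]:
    """Read a dataset written by :func:`save_patch_dataset`."""
    from pathlib import Path

    import tifffile

    from .io import read_manifest

    directory = Path(directory)
    out = []
    for row in read_manifest(directory / "manifest.tsv"):
        stack = np.moveaxis(tifffile.imread(directory / row["file"]), 0, -1)
        channels, target = stack[..., :2], stack[..., 2:5]
        if row["weights"] == "per-pixel":
            weights = stack[..., 5 : 5 + int(row["n_stains"])]
        else:
            weights = np.array([float(v) for v in row["weights"].split(",")])
        out.append(
            PatchPair(
                channels=channels,
                target=target,
                weights=weights,
                row=int(row["row"]),
                col=int(row["col"]),
                slide_id=int(row["slide_id"]),
            )
        )
    return out


def dihedral(arr: np.ndarray, k: int) -> np.ndarray:
    """Apply element k of the dihedral group D4 (k in 0..7) to an image.

    k % 4 counts quarter rotations; k >= 4 adds a left-right flip (applied
    before rotation).  k = 0 is the identity.
    """
    if not 0 <= k <= 7:
        raise ValueError("dihedral element index must be in 0..7")
    out = arr[:, ::-1] if k >= 4 else arr
    return np.rot90(out, k % 4)


def dihedral_inverse(k: int) -> int:
    """Index of the inverse group element of :func:`dihedral`."""
    if k < 4:
        return (-k) % 4
    return k  # each flip-then-rotate element is an involution


def augment(patch: PatchPair, seed: int | None = None, k: int | None = None) -> PatchPair:
    """One of the eight dihedral transforms applied to all planes of a patch.

    Either pass the group element ``k`` directly or a ``seed`` from which it
    is drawn.  Per-pixel staining matrices are transformed identically, so
    the sum-to-one rule is preserved pixel-by-pixel.
    """
    if patch.channels.shape[0] != patch.channels.shape[1]:
        raise ValueError("augmentation requires square patches")
    if k is None:
        if seed is None:
            raise ValueError("provide seed or k")
        k = int(np.random.default_rng(seed).integers(0, 8))
    weights = dihedral(patch.weights, k) if patch.weights.ndim == 3 else patch.weights.copy()
    return PatchPair(
        channels=np.ascontiguousarray(dihedral(patch.channels, k)),
        target=np.ascontiguousarray(dihedral(patch.target, k)),
        weights=np.ascontiguousarray(weights),
        row=patch.row,
        col=patch.col,
        slide_id=patch.slide_id,
    )
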