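"""Paired phantom data with known ground truth.

Real training data for virtual staining consists of co-registered pairs of
two-channel autofluorescence images (DAPI-like and Texas-Red-like) and
bright-field images of the same tissue after histochemical staining.  No
such data ships with this package; instead this module generates tissue
phantoms with a known structure label map (background / nucleus / membrane /
cytoplasm), renders the two autofluorescence channels from it, and renders
deterministic per-stain "oracle" bright-field targets so that conditional
recovery can be verified exactly.

The phantoms emulate the geometry that makes the staining problem learnable
— nuclei visible mainly in the DAPI-like channel, membranes and cytoplasm
in the Texas-Red-like channel, stain-specific colours per structure — but
none of the optics: no point-spread function, no autofluorescence spectra,
no staining chemistry, no scanner artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .color import rgb_to_ycbcr, to_uint8, ycbcr_to_rgb
from .staining_matrix import StainClass

BACKGROUND, NUCLEUS, MEMBRANE, CYTOPLASM = 0, 1, 2, 3
LABELS = (BACKGROUND, NUCLEUS, MEMBRANE, CYTOPLASM)

DEFAULT_STAINS = ("HE", "MT", "JS")


@dataclass
class Phantom:
    """A synthetic tissue section with known structure.

    ``channels`` are the noisy autofluorescence planes the network sees;
    ``clean_channels`` are the noise-free planes the oracle renderings are
    computed from, so targets carry a clean signal.
    """

    labels: np.ndarray  # (H, W) int, values in LABELS
    channels: np.ndarray  # (H, W, 2) float, noisy
    clean_channels: np.ndarray  # (H, W, 2) float
    seed: int


# Per-stain, per-structure RGB colours and contrast weights.  The palettes
# loosely mimic the real stains (H&E: purple nuclei / pink cytoplasm;
# trichrome: blue-green fibrous structures / red cytoplasm; silver: dark
# membranes on a pale counterstain) purely for interpretability — they are
# fixed constants, not a model of stain chemistry.
_ORACLE_RGB: dict[str, dict[int, tuple[tuple[float, float, float], float]]] = {
    "HE": {
        BACKGROUND: ((255, 255, 255), 0.05),
        NUCLEUS: ((72, 39, 117), 1.0),
        MEMBRANE: ((205, 115, 150), 0.8),
        CYTOPLASM: ((228, 132, 163), 0.9),
    },
    "MT": {
        BACKGROUND: ((255, 255, 255), 0.05),
        NUCLEUS: ((55, 35, 60), 1.0),
        MEMBRANE: ((60, 110, 165), 1.0),
        CYTOPLASM: ((190, 80, 90), 0.9),
    },
    "JS": {
        BACKGROUND: ((255, 255, 255), 0.05),
        NUCLEUS: ((90, 100, 90), 0.9),
        MEMBRANE: ((30, 30, 30), 1.0),
        CYTOPLASM: ((200, 205, 190), 0.7),
    },
}


@dataclass
class OracleStainTable:
    """Structure label -> (YCbCr colour, contrast weight) for one stain."""

    name: str
    colors: dict[int, np.ndarray]  # label -> YCbCr triple (0..255)
    contrast: dict[int, float]

    @classmethod
    def default(cls, name: str) -> "OracleStainTable":
        if name not in _ORACLE_RGB:
            raise KeyError(f"no built-in oracle table for stain {name!r}")
        colors = {
            lab: rgb_to_ycbcr(np.array(rgb, dtype=float))
            for lab, (rgb, _) in _ORACLE_RGB[name].items()
        }
        contrast = {lab: w for lab, (_, w) in _ORACLE_RGB[name].items()}
        return cls(name=name, colors=colors, contrast=contrast)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Band-limited random field, normalized to [0, 1]."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (f - lo) / (hi - lo)


def generate_phantom(
    seed: int,
    height: int = 256,
    width: int = 256,
    nucleus_density: float = 8e-4,
    cytoplasm_fraction: float = 0.55,
    noise_sigma: float = 0.02,
) -> Phantom:
    """Generate one phantom: label map plus two autofluorescence channels.

    ``nucleus_density`` is nuclei per pixel of tissue; ``cytoplasm_fraction``
    the approximate tissue coverage of the frame.  ``density`` parameters of
    zero produce a pure background phantom.
    """
    if height < 64 or width < 64:
        raise ValueError(f"phantom must be at least 64x64, got {height}x{width}")
    rng = np.random.default_rng(seed)
    labels = np.full((height, width), BACKGROUND, dtype=np.int8)

    if cytoplasm_fraction > 0:
        blob = _smooth_noise(rng, (height, width), sigma=min(height, width) / 12)
        thresh = np.quantile(blob, 1.0 - cytoplasm_fraction)
        tissue = blob >= thresh
        labels[tissue] = CYTOPLASM
        # membranes: ridges along tissue-region boundaries, 2-3 px thick
        boundary = tissue ^ ndimage.binary_erosion(tissue, iterations=2)
        # plus curvilinear internal ridges from a second band-limited field
        ridge_field = _smooth_noise(rng, (height, width), sigma=min(height, width) / 20)
        ridges = np.abs(ridge_field - 0.5) < 0.015
        labels[(boundary | (ridges & tissue))] = MEMBRANE
    else:
        tissue = np.zeros((height, width), dtype=bool)

    n_nuclei = rng.poisson(nucleus_density * tissue.sum()) if tissue.any() else 0
    if n_nuclei:
        rows, cols = np.nonzero(tissue)
        pick = rng.choice(len(rows), size=n_nuclei, replace=True)
        for r, c in zip(rows[pick], cols[pick]):
            a = rng.uniform(2.5, 6.0)
            b = rng.uniform(2.5, 6.0)
            theta = rng.uniform(0, np.pi)
            rad = int(np.ceil(max(a, b)))
            r0, r1 = max(0, r - rad), min(height, r + rad + 1)
            c0, c1 = max(0, c - rad), min(width, c + rad + 1)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            dy, dx = yy - r, xx - c
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            labels[r0:r1, c0:c1][(u / a) ** 2 + (v / b) ** 2 <= 1.0] = NUCLEUS

    texture = 0.7 + 0.3 * _smooth_noise(rng, (height, width), sigma=4)
    nucleus = labels == NUCLEUS
    membrane = labels == MEMBRANE
    cyto = labels == CYTOPLASM
    dapi = 0.03 + 0.9 * nucleus * texture + 0.32 * (cyto | membrane) * texture
    txred = 0.03 + 0.85 * membrane * texture + 0.45 * cyto * texture + 0.15 * nucleus
    clean = np.stack([dapi, txred], axis=-1).astype(np.float64)
    noisy = clean + rng.normal(0.0, noise_sigma, clean.shape)
    return Phantom(labels=labels, channels=np.clip(noisy, 0, None), clean_channels=clean, seed=seed)


def oracle_stain(
    phantom: Phantom,
    stain: StainClass | str,
    table: OracleStainTable | None = None,
    space: str = "rgb",
) -> np.ndarray:
    """Deterministic bright-field rendering of a phantom under one stain.

    Each pixel takes the stain's colour for its structure label, pulled
    toward white (bright-field convention) according to the structure's
    contrast weight and the phantom's clean channel intensity at that pixel.
    Returns an (H, W, 3) uint8 RGB image (or float YCbCr with
    ``space="ycbcr"``).
    """
    name = stain if isinstance(stain, str) else stain.name
    table = table or OracleStainTable.default(name)
    labels = phantom.labels
    h, w = labels.shape
    missing = set(np.unique(labels)) - set(table.colors)
    if missing:
        raise KeyError(f"oracle table {table.name!r} lacks labels {sorted(missing)}")
    white = rgb_to_ycbcr(np.array([255.0, 255.0, 255.0]))
    out = np.empty((h, w, 3), dtype=np.float64)
    dapi = phantom.clean_channels[..., 0]
    txred = phantom.clean_channels[..., 1]
    intensity = np.where(labels == NUCLEUS, dapi, txred)
    for lab in np.unique(labels):
        m = labels == lab
        depth = np.clip(table.contrast[int(lab)] * intensity[m] / 0.9, 0.0, 1.0)
        out[m] = white + (table.colors[int(lab)] - white) * depth[:, None]
    if space == "ycbcr":
        return out
    return to_uint8(ycbcr_to_rgb(out))


def oracle_blend(
    phantom: Phantom,
    weights: Sequence[float],
    stains: Sequence[str] = DEFAULT_STAINS,
    space: str = "rgb",
) -> np.ndarray:
    """Pixel-wise convex combination of the pure oracle renderings."""
    weights = np.asarray(weights, dtype=float)
    acc = np.zeros((*phantom.labels.shape, 3))
    for wgt, name in zip(weights, stains):
        if wgt:
            acc += wgt * oracle_stain(phantom, name, space="ycbcr")
    if space == "ycbcr":
        return acc
    return to_uint8(ycbcr_to_rgb(acc))


@dataclass
class SlideRecord:
    """One synthetic slide: phantom seed, stain assignment and split."""

    slide_id: int
    seed: int
    stain_index: int  # 1-based
    stain_name: str
    split: str
    height: int
    width: int


def make_dataset(
    n_slides: int,
    stains: Sequence[str] = DEFAULT_STAINS,
    seed: int = 0,
    size: int = 256,
    splits: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> dict[str, list[SlideRecord]]:
    """Slide-disjoint train/val/test manifests with round-robin stains.

    Mirrors the patient-disjoint protocol of real studies: a slide (and all
    patches cut from it) appears in exactly one split.
    """
    if n_slides < 3:
        raise ValueError("need at least 3 slides to populate all three splits")
    rng = np.random.default_rng(seed)
    slide_seeds = rng.integers(0, 2**31 - 1, size=n_slides)
    order = rng.permutation(n_slides)
    n_train = max(1, int(round(splits[0] * n_slides)))
    n_val = max(1, int(round(splits[1] * n_slides)))
    n_val = min(n_val, n_slides - n_train - 1)
    manifests: dict[str, list[SlideRecord]] = {"train": [], "val": [], "test": []}
    for pos, idx in enumerate(order):
        split = "train" if pos < n_train else "val" if pos < n_train + n_val else "test"
        stain_index = (int(idx) % len(stains)) + 1
        manifests[split].append(
            SlideRecord(
                slide_id=int(idx),
                seed=int(slide_seeds[idx]),
                stain_index=stain_index,
                stain_name=stains[stain_index - 1],
                split=split,
                height=size,
                width=size,
            )
        )
    return manifests


def materialize_slide(rec: SlideRecord, normalize: bool = True):
    """Realize a manifest record as a registered, normalized slide pair.

    Returns ``(SlidePair, Phantom)``: the phantom's noisy channels are
    tissue-masked and standardized per channel, the oracle rendering of the
    assigned stain becomes the YCbCr target scaled to [0, 1], and the stain
    assignment becomes a one-hot weight vector.
    """
    from .preprocessing import SlidePair, normalize_slide, tissue_mask

    phantom = generate_phantom(rec.seed, rec.height, rec.width)
    mask = tissue_mask(phantom.channels[..., 0])
    if normalize:
        channels = np.stack(
            [normalize_slide(phantom.channels[..., k], mask) for k in range(2)], axis=-1
        )
    else:
        channels = phantom.channels
    target = oracle_stain(phantom, rec.stain_name, space="ycbcr") / 255.0
    weights = np.zeros(3)
    weights[rec.stain_index - 1] = 1.0
    pair = SlidePair(channels=channels, target=target, mask=mask, weights=weights)
    return pair, phantom


def build_patch_dataset(
    records: Sequence[SlideRecord],
    patch: int = 64,
    stride: int = 32,
    seed: int = 0,
    augment_patches: bool = True,
):
    """Cut manifest slides into augmented training patches."""
    from .preprocessing import augment, extract_patches

    out = []
    for rec in records:
        pair, _ = materialize_slide(rec)
        patches = extract_patches(
            pair, size=patch, stride=stride, seed=seed + rec.slide_id, slide_id=rec.slide_id
        )
        if augment_patches:
            patches = [
                augment(p, seed=seed + rec.slide_id * 1000 + i)
                for i, p in enumerate(patches)
            ]
        out.extend(patches)
    return out


def synthetic_warp(
    image: np.ndarray,
    seed: int,
    amplitude: float,
    smoothness: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp an image with a smooth random displacement field.

    Returns ``(warped, field)`` where ``warped(p) = image(p + field(p))``
    (bilinear sampling, edge clamped), so registering ``image`` (reference)
    against ``warped`` (moving) should recover ``field``.  The field is
    band-limited white noise smoothed with a Gaussian of sigma
    ``smoothness * min(H, W)`` and scaled so its maximum magnitude equals
    ``amplitude``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    field = np.zeros((h, w, 2))
    if amplitude > 0:
        rng = np.random.default_rng(seed)
        sigma = smoothness * min(h, w)
        for k in range(2):
            field[..., k] = ndimage.gaussian_filter(
                rng.normal(size=(h, w)), sigma, mode="reflect"
            )
        mag = np.sqrt((field**2).sum(-1)).max()
        if mag > 0:
            field *= amplitude / mag
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    warped = ndimage.map_coordinates(
        image, [rows + field[..., 0], cols + field[..., 1]], order=1, mode="nearest"
    )
    return warped, field
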