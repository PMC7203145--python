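"""Raster I/O: grayscale/stack TIFF, PNG export, displacement fields, manifests."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .registration import DisplacementField


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG as a float array (grayscale 2-D or channels-last)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        # multi-plane TIFF stacks come in plane-first order
        if arr.ndim == 3 and arr.shape[0] in (2, 3, 4) and arr.shape[0] < arr.shape[-1]:
            arr = np.moveaxis(arr, 0, -1)
        return np.asarray(arr, dtype=np.float64)
    return np.asarray(Image.open(path), dtype=np.float64)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write float stacks as 32-bit TIFF, uint8 images as PNG/TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = image
        if arr.ndim == 3:
            arr = np.moveaxis(arr, -1, 0)  # plane-first for TIFF stacks
        if arr.dtype != np.uint8:
            arr = arr.astype(np.float32)
        tifffile.imwrite(path, arr)
    else:
        if image.dtype != np.uint8:
            raise ValueError("PNG export expects uint8; convert first")
        Image.fromarray(image).save(path)


def write_field(path: str | Path, field: DisplacementField) -> None:
    """Persist a displacement field as a 2-plane 32-bit TIFF."""
    write_image(Path(path), field.shifts.astype(np.float32))


def read_field(path: str | Path) -> DisplacementField:
    arr = read_image(path)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError(f"expected a 2-plane field TIFF, got shape {arr.shape}")
    return DisplacementField(arr)


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    """Write a list of records as TSV with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not rows:
        path.write_text("")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
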