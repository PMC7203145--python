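"""The digital staining matrix: per-pixel stain-condition weights.

The conditioning object of the whole framework is a stack of N_stains planes
c~ = [c1, ..., cN], one weight per stain per pixel, concatenated to the
two autofluorescence channels at the network input.  Single stains are
one-hot planes, blends are fractional constant planes, and micro-structured
staining assigns different weight vectors to user-drawn regions of interest.

Every construction path enforces the encoding rule that at each pixel the
weights are non-negative and sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely

SUM_TOL = 1e-6


class EncodingRuleError(ValueError):
    """A staining matrix violates the per-pixel sum-to-one / range rule."""


class InvalidStainError(ValueError):
    """A stain index is outside [1, n_stains] or a stain name is unknown."""


class AnnotationError(ValueError):
    """A polygon annotation is malformed (too few vertices, bad JSON, ...)."""


@dataclass(frozen=True)
class StainClass:
    """One stain type: 1-based index into the staining-matrix planes."""

    index: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InvalidStainError(f"stain index must be >= 1, got {self.index}")


@dataclass
class DigitalStainingMatrix:
    """Per-pixel stain weights, shape (height, width, n_stains) in [0, 1]."""

    weights: np.ndarray
    stain_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise EncodingRuleError(
                f"weights must be (height, width, n_stains), got shape {self.weights.shape}"
            )
        if self.stain_names and len(self.stain_names) != self.n_stains:
            raise InvalidStainError(
                f"{len(self.stain_names)} stain names for {self.n_stains} planes"
            )

    @property
    def height(self) -> int:
        return self.weights.shape[0]

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def n_stains(self) -> int:
        return self.weights.shape[2]

    def check(self) -> "DigitalStainingMatrix":
        """Raise :class:`EncodingRuleError` unless the matrix validates."""
        violations = validate(self)
        if violations:
            raise EncodingRuleError(
                f"{len(violations)} pixels violate the staining-matrix encoding rule; "
                f"first: {violations[0]}"
            )
        return self


@dataclass
class RoiSpec:
    """Polygonal regions of interest, each carrying a stain-weight vector.

    ``polygons`` is a list of (vertices, weights) pairs where vertices are
    (x, y) = (col, row) pixel coordinates; pixels covered by no polygon take
    ``default_weights``.  On (malformed, overlapping) input the last-listed
    polygon wins.
    """

    polygons: list[tuple[np.ndarray, np.ndarray]]
    default_weights: np.ndarray

    def __post_init__(self) -> None:
        self.default_weights = _check_weight_vector(np.asarray(self.default_weights))
        checked = []
        for verts, w in self.polygons:
            verts = np.asarray(verts, dtype=np.float64)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise AnnotationError(
                    f"polygon needs >= 3 (x, y) vertices, got array of shape {verts.shape}"
                )
            poly = shapely.Polygon(verts)
            if not poly.is_valid:
                raise AnnotationError(f"polygon is not simple/valid: {shapely.is_valid_reason(poly)}")
            checked.append((verts, _check_weight_vector(np.asarray(w))))
        self.polygons = checked

    @property
    def n_stains(self) -> int:
        return len(self.default_weights)


def _check_weight_vector(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 1:
        raise EncodingRuleError(f"weight vector must be 1-D, got shape {w.shape}")
    if np.any(w < 0):
        raise EncodingRuleError(f"stain weights must be non-negative, got {w}")
    s = float(w.sum())
    if abs(s - 1.0) > SUM_TOL:
        raise EncodingRuleError(f"stain weights must sum to 1 (got {s:.8f}): {w}")
    return w


def one_hot_matrix(
    stain: StainClass | int,
    height: int,
    width: int,
    n_stains: int,
    stain_names: Sequence[str] = (),
) -> DigitalStainingMatrix:
    """All-ones plane for one stain, zeros elsewhere (single-stain condition)."""
    index = stain.index if isinstance(stain, StainClass) else int(stain)
    if not 1 <= index <= n_stains:
        raise InvalidStainError(f"stain index {index} outside [1, {n_stains}]")
    if height <= 0 or width <= 0:
        raise ValueError(f"image size must be positive, got {height}x{width}")
    w = np.zeros((height, width, n_stains))
    w[:, :, index - 1] = 1.0
    return DigitalStainingMatrix(w, stain_names)


def blend_matrix(
    weights: Sequence[float],
    height: int,
    width: int,
    stain_names: Sequence[str] = (),
) -> DigitalStainingMatrix:
    """Spatially uniform blend: every pixel carries the given weight vector."""
    w = _check_weight_vector(np.asarray(weights))
    if height <= 0 or width <= 0:
        raise ValueError(f"image size must be positive, got {height}x{width}")
    grid = np.broadcast_to(w, (height, width, len(w))).copy()
    return DigitalStainingMatrix(grid, stain_names)


def roi_matrix(
    spec: RoiSpec,
    height: int,
    width: int,
    stain_names: Sequence[str] = (),
) -> DigitalStainingMatrix:
    """Rasterize an :class:`RoiSpec` into a per-pixel staining matrix.

    A pixel belongs to a polygon when its center (col + 0.5 would be the
    pixel's right edge; centers sit at integer coordinates (x, y) = (col,
    row)) lies inside the polygon; later polygons overwrite earlier ones on
    overlap.
    """
    grid = np.broadcast_to(
        spec.default_weights, (height, width, spec.n_stains)
    ).copy()
    if not spec.polygons:
        return DigitalStainingMatrix(grid, stain_names)
    cols, rows = np.meshgrid(np.arange(width, dtype=float), np.arange(height, dtype=float))
    for verts, w in spec.polygons:
        if len(w) != spec.n_stains:
            raise EncodingRuleError(
                f"polygon weight vector length {len(w)} != n_stains {spec.n_stains}"
            )
        poly = shapely.Polygon(verts)
        inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel()).reshape(height, width)
        grid[inside] = w
    return DigitalStainingMatrix(grid, stain_names)


def validate(dsm: DigitalStainingMatrix) -> list[dict]:
    """Report every pixel violating the encoding rule (empty list = valid).

    Each record carries the pixel location, the offending weight sum and, for
    range violations, the out-of-range entries.
    """
    w = dsm.weights
    violations: list[dict] = []
    bad_range = np.any((w < 0) | (w > 1), axis=2)
    sums = w.sum(axis=2)
    bad_sum = np.abs(sums - 1.0) > SUM_TOL
    for r, c in zip(*np.nonzero(bad_range | bad_sum)):
        rec: dict = {"row": int(r), "col": int(c), "sum": float(sums[r, c])}
        if bad_range[r, c]:
            rec["out_of_range"] = w[r, c].tolist()
        violations.append(rec)
    return violations


def read_polygon_annotations(
    path: str | Path,
    label_weights: Mapping[str, Sequence[float]],
    default_label: str | None = None,
    default_weights: Sequence[float] | None = None,
) -> RoiSpec:
    """Read a polygon-annotation JSON file (labelme-style) into an RoiSpec.

    The file must hold a top-level ``"shapes"`` list of
    ``{"label": str, "points": [[x, y], ...], "shape_type": "polygon"}``.
    ``label_weights`` maps each label to its stain-weight vector; pixels in no
    shape take ``default_weights`` (or the weights of ``default_label``).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path} is not valid annotation JSON: {exc}") from exc
    shapes = doc.get("shapes")
    if shapes is None or not isinstance(shapes, list):
        raise AnnotationError(f'{path} has no "shapes" list')
    if default_weights is None:
        if default_label is None:
            raise ValueError("provide default_weights or default_label")
        if default_label not in label_weights:
            raise InvalidStainError(f"default label {default_label!r} not in mapping")
        default_weights = label_weights[default_label]
    polygons = []
    for shape in shapes:
        if shape.get("shape_type", "polygon") != "polygon":
            raise AnnotationError(f"unsupported shape_type {shape.get('shape_type')!r}")
        label = shape.get("label")
        if label not in label_weights:
            raise InvalidStainError(
                f"label {label!r} has no stain-weight mapping "
                f"(known: {sorted(label_weights)})"
            )
        points = np.asarray(shape.get("points", []), dtype=np.float64)
        if points.ndim != 2 or points.shape[0] < 3:
            raise AnnotationError(
                f"shape labelled {label!r} has {0 if points.ndim != 2 else points.shape[0]} "
                "vertices; a polygon needs at least 3"
            )
        polygons.append((points, np.asarray(label_weights[label], dtype=np.float64)))
    return RoiSpec(polygons=polygons, default_weights=np.asarray(default_weights, float))
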