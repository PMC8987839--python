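"""Chopping rectangle annotations into overlapping square training patches.

The weak-supervision trick at the heart of the pipeline: a human draws a
handful of labeled rectangles per image, and each rectangle is chopped
into many 32x32 patches on a 16-pixel stride (50% overlap both ways).
A few hundred rectangles thus yield tens of thousands of labeled training
tiles at almost no annotation cost.

Coordinates are 0-based half-open throughout.  Windows that would poke
out of their rectangle are discarded rather than padded — padding would
fabricate pixels.  For a rectangle of size W x H with patch p and stride
s, the emitted patch count is::

    max(0, (W - p) // s + 1) * max(0, (H - p) // s + 1)
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import AnnotationError, InputError


@dataclass(frozen=True)
class RectAnnotation:
    """A labeled axis-aligned box ``[x0, x1) x [y0, y1)`` on a source image."""

    image_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    label: bool

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise AnnotationError(
                f"empty rectangle {self.box} on image {self.image_id!r}"
            )

    @property
    def box(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass(frozen=True)
class ChopParams:
    """Patch size and stride; the defaults give 50% overlap."""

    patch_px: int = 32
    stride_px: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.stride_px <= self.patch_px):
            raise InputError(
                f"need 0 < stride ({self.stride_px}) <= patch ({self.patch_px})"
            )


@dataclass(frozen=True)
class Patch:
    """One training tile: float32 RGB pixels in [0, 1], its label, and
    the (image_id, x, y) of its top-left corner in the source image."""

    pixels: np.ndarray
    label: bool
    source: tuple[str, int, int]


@dataclass(frozen=True)
class PatchSet:
    patches: tuple[Patch, ...]
    n_positive: int
    n_negative: int

    def __len__(self) -> int:
        return len(self.patches)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into ``(X, y)`` — X of shape (n, p, p, 3) float32, y bool."""
        if not self.patches:
            p = ChopParams().patch_px
            return np.empty((0, p, p, 3), np.float32), np.empty(0, bool)
        X = np.stack([p.pixels for p in self.patches])
        y = np.array([p.label for p in self.patches], dtype=bool)
        return X, y


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an RGB (H, W, 3) raster, got shape {image.shape}")
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32)


def chop_rectangle(
    image: np.ndarray, rect: RectAnnotation, params: ChopParams = ChopParams()
) -> list[Patch]:
    """Slide a ``patch_px`` window over ``rect`` at ``stride_px`` and emit
    every fully-contained tile, each inheriting the rectangle's label.
    Tiles come out in row-major order (top-to-bottom, left-to-right)."""
    img = _as_float_rgb(image)
    h, w = img.shape[:2]
    if rect.x0 < 0 or rect.y0 < 0 or rect.x1 > w or rect.y1 > h:
        raise AnnotationError(
            f"rectangle {rect.box} on image {rect.image_id!r} exceeds its "
            f"{w}x{h} source image"
        )
    p, s = params.patch_px, params.stride_px
    patches: list[Patch] = []
    for y in range(rect.y0, rect.y1 - p + 1, s):
        for x in range(rect.x0, rect.x1 - p + 1, s):
            tile = np.ascontiguousarray(img[y : y + p, x : x + p])
            patches.append(Patch(tile, rect.label, (rect.image_id, x, y)))
    return patches


def expected_patch_count(rect: RectAnnotation, params: ChopParams = ChopParams()) -> int:
    """Closed-form count of tiles :func:`chop_rectangle` emits."""
    p, s = params.patch_px, params.stride_px
    nx = max(0, (rect.width - p) // s + 1)
    ny = max(0, (rect.height - p) // s + 1)
    return nx * ny


def build_patchset(
    images: Mapping[str, np.ndarray],
    annotations: Sequence[RectAnnotation],
    params: ChopParams = ChopParams(),
    screen_masks: Mapping[str, np.ndarray] | None = None,
    screen_occupancy: float = 0.5,
) -> PatchSet:
    """Chop every annotation and pool the tiles into one training set.

    Ordering is stable: annotation order, then row-major tile order
    within each rectangle.

    ``screen_masks`` optionally supplies per-image ground-truth greenery
    masks (synthetic data only); when present, positive tiles whose true
    greenery fraction does not exceed ``screen_occupancy`` are dropped,
    and likewise negative tiles with too much greenery — an automated
    version of manually discarding patches less than half covered by
    their target object.  Real annotations have no mask and are trusted
    as labeled.
    """
    missing = sorted({a.image_id for a in annotations} - set(images))
    if missing:
        raise InputError(f"annotations reference absent images: {missing}")

    patches: list[Patch] = []
    for rect in annotations:
        tiles = chop_rectangle(images[rect.image_id], rect, params)
        if screen_masks is not None and rect.image_id in screen_masks:
            mask = np.asarray(screen_masks[rect.image_id], dtype=bool)
            p = params.patch_px
            kept = []
            for t in tiles:
                _, x, y = t.source
                frac = mask[y : y + p, x : x + p].mean()
                ok = frac > screen_occupancy if t.label else frac <= screen_occupancy
                if ok:
                    kept.append(t)
            tiles = kept
        patches.extend(tiles)

    n_pos = sum(1 for p in patches if p.label)
    return PatchSet(tuple(patches), n_positive=n_pos, n_negative=len(patches) - n_pos)


# ---------------------------------------------------------------------------
# annotation CSV dialect: image_id,x0,y0,x1,y1,label (header required)

_HEADER = ["image_id", "x0", "y0", "x1", "y1", "label"]


def write_annotations(annotations: Iterable[RectAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for a in annotations:
            writer.writerow([a.image_id, a.x0, a.y0, a.x1, a.y1, int(a.label)])


def read_annotations(path: str | Path) -> list[RectAnnotation]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _HEADER:
            raise InputError(
                f"annotation CSV {path} must have header {','.join(_HEADER)}"
            )
        return [
            RectAnnotation(
                row["image_id"],
                int(row["x0"]),
                int(row["y0"]),
                int(row["x1"]),
                int(row["y1"]),
                bool(int(row["label"])),
            )
            for row in reader
        ]
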