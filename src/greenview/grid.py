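"""Whole-image grid classification and the per-image Green View Index.

At inference the streetscape is tiled into *non-overlapping* 32-pixel
square cells from the top-left corner (a 640x640 image gives the
canonical 20x20 grid; remainder pixels are truncated, never padded).
Each cell is classified by the trained patch model at its decision
threshold, and the Green View Index of the image is the percentage of
positive cells.  Overlap is a training-time device only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import InputError


@dataclass(frozen=True)
class GridClassification:
    """Per-image boolean cell mask with bookkeeping."""

    image_id: str
    rows: int
    cols: int
    cell_px: int
    cell_mask: np.ndarray  # (rows, cols) bool

    def __post_init__(self) -> None:
        if self.cell_mask.shape != (self.rows, self.cols):
            raise InputError(
                f"cell_mask shape {self.cell_mask.shape} != ({self.rows}, {self.cols})"
            )

    @property
    def positive_count(self) -> int:
        return int(self.cell_mask.sum())

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class ImageGVI:
    image_id: str
    district_id: str
    gvi_percent: float


def _tile_cells(image: np.ndarray, cell_px: int) -> tuple[np.ndarray, int, int]:
    """Cut an (H, W, 3) raster into (rows*cols, cell_px, cell_px, 3) tiles,
    row-major, truncating the remainder."""
    if cell_px <= 0:
        raise InputError(f"cell_px must be positive, got {cell_px}")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an RGB (H, W, 3) raster, got shape {image.shape}")
    h, w = image.shape[:2]
    rows, cols = h // cell_px, w // cell_px
    if rows == 0 or cols == 0:
        raise InputError(f"image {h}x{w} smaller than one {cell_px}px cell")
    trimmed = image[: rows * cell_px, : cols * cell_px]
    tiles = (
        trimmed.reshape(rows, cell_px, cols, cell_px, 3)
        .swapaxes(1, 2)
        .reshape(rows * cols, cell_px, cell_px, 3)
    )
    return np.ascontiguousarray(tiles), rows, cols


def classify_grid(
    image: np.ndarray,
    model,
    cell_px: int = 32,
    image_id: str = "",
) -> GridClassification:
    """Tile ``image`` into disjoint cells and classify each with ``model``.

    ``model`` needs a ``greenery_probability(tiles) -> (n,)`` method plus a
    ``decision_threshold`` attribute (:class:`~greenview.classifier.
    PatchCNNClassifier` or any stub honoring that contract).
    """
    tiles, rows, cols = _tile_cells(image, cell_px)
    if tiles.dtype == np.uint8:
        tiles = tiles.astype(np.float32) / 255.0
    prob = np.asarray(model.greenery_probability(tiles))
    threshold = getattr(model, "decision_threshold", 0.5)
    cell_mask = (prob >= threshold).reshape(rows, cols)
    return GridClassification(
        image_id=image_id, rows=rows, cols=cols, cell_px=cell_px, cell_mask=cell_mask
    )


def grid_from_mask(
    mask_grid: np.ndarray, image_id: str = "", cell_px: int = 32
) -> GridClassification:
    """Wrap an already-computed boolean cell grid (e.g. ground-truth
    occupancy labels) in a :class:`GridClassification`."""
    mask_grid = np.asarray(mask_grid, dtype=bool)
    if mask_grid.ndim != 2 or mask_grid.size == 0:
        raise InputError(f"expected a non-empty 2-D cell grid, got {mask_grid.shape}")
    return GridClassification(
        image_id=image_id,
        rows=mask_grid.shape[0],
        cols=mask_grid.shape[1],
        cell_px=cell_px,
        cell_mask=mask_grid,
    )


def gvi_of_grid(grid: GridClassification) -> float:
    """Green View Index: percentage of positive cells, full precision
    (format to two decimals at I/O boundaries only)."""
    if grid.n_cells == 0:
        raise InputError("cannot compute GVI of a zero-cell grid")
    return 100.0 * grid.positive_count / grid.n_cells


def render_overlay(
    image: np.ndarray,
    grid: GridClassification,
    alpha: float = 0.35,
) -> np.ndarray:
    """Presentational overlay: translucent red over greenery cells, green
    over the rest, with 1-pixel grid lines.  Pixels outside the tiled area
    (truncated remainder) are left untouched."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an RGB raster, got shape {image.shape}")
    h, w = image.shape[:2]
    if h < grid.rows * grid.cell_px or w < grid.cols * grid.cell_px:
        raise InputError(
            f"image {h}x{w} cannot hold a {grid.rows}x{grid.cols} grid of "
            f"{grid.cell_px}px cells"
        )
    out = image.astype(np.float32).copy()
    red = np.array([255.0, 0.0, 0.0])
    green = np.array([0.0, 200.0, 0.0])
    cp = grid.cell_px
    for r in range(grid.rows):
        for c in range(grid.cols):
            tint = red if grid.cell_mask[r, c] else green
            block = out[r * cp : (r + 1) * cp, c * cp : (c + 1) * cp]
            block *= 1.0 - alpha
            block += alpha * tint
            block[0, :] = block[:, 0] = 60.0  # grid lines
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


class MaskOracleModel:
    """A "perfect" stand-in model that classifies a cell positive when the
    ground-truth greenery mask occupies more than ``occupancy_threshold``
    of it — the plumbing oracle tying grid inference back to the
    occupancy rule on synthetic fixtures."""

    decision_threshold = 0.5

    def __init__(self, mask: np.ndarray, occupancy_threshold: float = 0.5):
        self.mask = np.asarray(mask, dtype=bool)
        self.occupancy_threshold = occupancy_threshold
        self._cursor = 0

    def attach(self, cell_px: int) -> "MaskOracleModel":
        """Precompute per-cell occupancy fractions in row-major order."""
        h, w = self.mask.shape
        rows, cols = h // cell_px, w // cell_px
        cells = self.mask[: rows * cell_px, : cols * cell_px].reshape(
            rows, cell_px, cols, cell_px
        )
        self._fracs = cells.mean(axis=(1, 3)).reshape(-1)
        self._cursor = 0
        return self

    def greenery_probability(self, tiles: np.ndarray) -> np.ndarray:
        n = tiles.shape[0]
        frac = self._fracs[self._cursor : self._cursor + n]
        self._cursor += n
        return (frac > self.occupancy_threshold).astype(np.float32)


# ---------------------------------------------------------------------------
# grid CSV dialect shared by predictions and reference grids: one row per
# image, cells serialized row-major as a 0/1 string

import csv as _csv
from pathlib import Path as _Path


def write_grid_csv(
    grids, path, district_ids: dict[str, str] | None = None
) -> None:
    """Write classifications as CSV: image_id, district_id, rows, cols,
    positive_count, gvi_percent (2 decimals), cells (row-major 0/1)."""
    district_ids = district_ids or {}
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(
            ["image_id", "district_id", "rows", "cols", "positive_count",
             "gvi_percent", "cells"]
        )
        for g in grids:
            cells = "".join("1" if v else "0" for v in g.cell_mask.reshape(-1))
            writer.writerow(
                [g.image_id, district_ids.get(g.image_id, ""), g.rows, g.cols,
                 g.positive_count, f"{gvi_of_grid(g):.2f}", cells]
            )


def read_grid_csv(path) -> list[GridClassification]:
    grids = []
    with open(path, newline="") as fh:
        for row in _csv.DictReader(fh):
            rows, cols = int(row["rows"]), int(row["cols"])
            cells = np.array([ch == "1" for ch in row["cells"]], dtype=bool)
            if cells.size != rows * cols:
                raise InputError(
                    f"grid CSV row for {row['image_id']!r} has {cells.size} "
                    f"cells, expected {rows * cols}"
                )
            grids.append(
                GridClassification(
                    image_id=row["image_id"], rows=rows, cols=cols,
                    cell_px=32, cell_mask=cells.reshape(rows, cols),
                )
            )
    return grids
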