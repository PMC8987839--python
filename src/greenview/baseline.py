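"""Color band-difference greenery baseline.

The classical unsupervised rule for street-level greenery: a pixel is
vegetation when its green channel exceeds both the red and the blue
channel by more than a threshold delta, on [0, 1]-scaled channels
(delta defaults to 0.05, i.e. about 12.75 digital numbers on 8-bit
imagery).  Purely spectral — which is exactly why it mistakes green
artificial objects and some shadows for vegetation, the failure mode the
texture-aware patch classifier is meant to fix.

Exposed both as plain functions and as a scikit-learn estimator
(:class:`ColorBandDifference`) operating on per-pixel RGB rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import remove_small_objects
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import InputError
from .grid import GridClassification, grid_from_mask
from .scenes import mask_to_grid_labels


@dataclass(frozen=True)
class ColorParams:
    """``delta``: band-difference threshold on [0, 1] channels;
    ``min_region_px``: drop connected greenery blobs smaller than this
    (4-connectivity); 0 disables despeckling."""

    delta: float = 0.05
    min_region_px: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise InputError(f"delta must be non-negative, got {self.delta}")
        if self.min_region_px < 0:
            raise InputError("min_region_px must be non-negative")


def _scaled_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(
            f"expected an RGB (H, W, 3) raster, got shape {image.shape}; "
            "convert grayscale input to RGB first"
        )
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    return image.astype(np.float64)


def color_classify_pixels(
    image: np.ndarray, params: ColorParams = ColorParams()
) -> np.ndarray:
    """Per-pixel greenery mask: true iff (G-R) > delta and (G-B) > delta."""
    rgb = _scaled_rgb(image)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mask = (g - r > params.delta) & (g - b > params.delta)
    if params.min_region_px > 0:
        # drop connected components with fewer than min_region_px pixels
        mask = remove_small_objects(
            mask, max_size=params.min_region_px - 1, connectivity=1
        )
    return mask


def color_mask_to_grid(
    mask: np.ndarray,
    cell_px: int = 32,
    occupancy_threshold: float = 0.5,
    image_id: str = "",
) -> GridClassification:
    """Put the baseline's pixel mask on the same cell-grid footing as the
    patch classifier, via the identical strict-majority occupancy rule."""
    grid = mask_to_grid_labels(
        mask, cell_px=cell_px, occupancy_threshold=occupancy_threshold
    )
    return grid_from_mask(grid, image_id=image_id, cell_px=cell_px)


def color_classify_grid(
    image: np.ndarray,
    params: ColorParams = ColorParams(),
    cell_px: int = 32,
    occupancy_threshold: float = 0.5,
    image_id: str = "",
) -> GridClassification:
    """Pixels then cells in one call — the baseline's analog of
    :func:`greenview.grid.classify_grid`."""
    return color_mask_to_grid(
        color_classify_pixels(image, params),
        cell_px=cell_px,
        occupancy_threshold=occupancy_threshold,
        image_id=image_id,
    )


class ColorBandDifference(ClassifierMixin, BaseEstimator):
    """sklearn-style view of the band-difference rule over pixel rows.

    A fixed rule, so ``fit`` only validates and records ``classes_``;
    ``predict`` takes ``(n, 3)`` RGB rows in [0, 1] (or uint8) and
    returns a boolean greenery label per row.
    """

    def __init__(self, delta: float = 0.05):
        self.delta = delta

    def fit(self, X=None, y=None) -> "ColorBandDifference":
        if self.delta < 0:
            raise InputError(f"delta must be non-negative, got {self.delta}")
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 3:
            raise InputError(f"expected (n, 3) RGB rows, got shape {X.shape}")
        if X.dtype == np.uint8:
            X = X.astype(np.float64) / 255.0
        r, g, b = X[:, 0], X[:, 1], X[:, 2]
        return (g - r > self.delta) & (g - b > self.delta)
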