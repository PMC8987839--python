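"""Synthetic streetscape scenes with known per-pixel greenery masks.

Real Green View Index surveys run on street-level photographs; nothing in
the pipeline below the image loader cares where the pixels came from, so
the whole chain — patch chopping, classifier training, grid inference,
the color baseline and the cell-wise evaluation — can be exercised on
synthetic scenes whose ground truth is known exactly.

A scene is a flat composition of axis-aligned rectangular regions, each
belonging to one of six streetscape categories:

``vegetation``
    green with strong high-frequency multiplicative luminance noise plus a
    mid-frequency blotch field (canopy-like texture),
``shadow_vegetation``
    vegetation texture with luminance scaled down into deep shadow,
``artificial_green``
    near-uniform green (turf, mats, painted surfaces) — *not* greenery,
``sky``
    vertical blue-to-white gradient,
``building`` / ``road``
    low-frequency gray surfaces.

The ground-truth greenery mask is derived from region *geometry* (later
regions overwrite earlier ones), never from rendered colors, so it is
independent of rendering noise.  Only ``vegetation`` and
``shadow_vegetation`` count as greenery; ``artificial_green`` deliberately
does not — texture, not color, separates the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from PIL import Image

from .exceptions import GenerationError, InputError, SceneSpecError

CATEGORIES = (
    "vegetation",
    "artificial_green",
    "shadow_vegetation",
    "sky",
    "building",
    "road",
)

#: categories whose pixels enter the ground-truth greenery mask
GREENERY_CATEGORIES = frozenset({"vegetation", "shadow_vegetation"})

_DEFAULT_BASE_COLOR = {
    "vegetation": (0.16, 0.42, 0.13),
    "shadow_vegetation": (0.16, 0.42, 0.13),
    "artificial_green": (0.22, 0.56, 0.20),
    "sky": (0.48, 0.66, 0.94),
    "building": (0.58, 0.56, 0.54),
    "road": (0.36, 0.36, 0.38),
}

# high-frequency multiplicative luminance noise amplitude per category
_DEFAULT_AMPLITUDE = {
    "vegetation": 0.25,
    "shadow_vegetation": 0.25,
    "artificial_green": 0.015,
    "sky": 0.0,
    "building": 0.03,
    "road": 0.03,
}


@dataclass(frozen=True)
class RegionSpec:
    """One rectangular region of a synthetic scene.

    ``box`` is ``(x0, y0, x1, y1)`` in 0-based half-open pixel
    coordinates.  ``texture_amplitude`` and ``base_color`` default to
    category-appropriate values when ``None``.
    """

    category: str
    box: tuple[int, int, int, int]
    texture_amplitude: float | None = None
    base_color: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SceneSpecError(
                f"unknown region category {self.category!r}; "
                f"expected one of {sorted(CATEGORIES)}"
            )
        x0, y0, x1, y1 = self.box
        if x1 <= x0 or y1 <= y0:
            raise SceneSpecError(f"degenerate region box {self.box}")

    @property
    def amplitude(self) -> float:
        if self.texture_amplitude is not None:
            return float(self.texture_amplitude)
        return _DEFAULT_AMPLITUDE[self.category]

    @property
    def color(self) -> tuple[float, float, float]:
        if self.base_color is not None:
            return tuple(float(c) for c in self.base_color)  # type: ignore[return-value]
        return _DEFAULT_BASE_COLOR[self.category]

    @property
    def is_greenery(self) -> bool:
        return self.category in GREENERY_CATEGORIES


@dataclass(frozen=True)
class SceneSpec:
    """Full specification of a synthetic scene; rendering is a pure
    deterministic function of this object."""

    width: int = 640
    height: int = 640
    regions: tuple[RegionSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise SceneSpecError(
                f"canvas must be positive, got {self.width}x{self.height}"
            )
        object.__setattr__(self, "regions", tuple(self.regions))
        for r in self.regions:
            x0, y0, x1, y1 = r.box
            if x0 < 0 or y0 < 0 or x1 > self.width or y1 > self.height:
                raise SceneSpecError(
                    f"region box {r.box} exceeds the {self.width}x{self.height} canvas"
                )


@dataclass(frozen=True)
class SceneFixture:
    """Rendered scene: 8-bit RGB image, boolean greenery mask, and the
    spec that produced both."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool
    spec: SceneSpec

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise SceneSpecError("image and mask dimensions differ")


def _low_frequency_field(rng: np.random.Generator, h: int, w: int, cell: int) -> np.ndarray:
    """Smooth zero-mean field from a coarse noise grid upsampled bilinearly."""
    gh = max(2, h // cell + 2)
    gw = max(2, w // cell + 2)
    coarse = rng.standard_normal((gh, gw))
    ys = np.linspace(0, gh - 1, h)
    xs = np.linspace(0, gw - 1, w)
    y0 = np.floor(ys).astype(int).clip(max=gh - 2)
    x0 = np.floor(xs).astype(int).clip(max=gw - 2)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    c00 = coarse[np.ix_(y0, x0)]
    c01 = coarse[np.ix_(y0, x0 + 1)]
    c10 = coarse[np.ix_(y0 + 1, x0)]
    c11 = coarse[np.ix_(y0 + 1, x0 + 1)]
    return (
        c00 * (1 - fy) * (1 - fx)
        + c01 * (1 - fy) * fx
        + c10 * fy * (1 - fx)
        + c11 * fy * fx
    )


def _render_region(
    region: RegionSpec, h: int, w: int, rng: np.random.Generator
) -> np.ndarray:
    """Render one region's pixels as an (h, w, 3) float block in [0, 1]."""
    base = np.asarray(region.color, dtype=np.float64)
    block = np.broadcast_to(base, (h, w, 3)).copy()
    cat = region.category

    if cat == "sky":
        # vertical gradient: base blue at the top, near-white at the bottom
        t = np.linspace(0.0, 1.0, h)[:, None, None]
        white = np.array([0.97, 0.98, 1.0])
        block = base * (1 - t) + white * t
        block = np.broadcast_to(block, (h, w, 3)).copy()
    elif cat in ("building", "road"):
        lowf = _low_frequency_field(rng, h, w, 48)
        block *= (1.0 + region.amplitude * 3.0 * lowf)[:, :, None]
    elif cat in ("vegetation", "shadow_vegetation"):
        # canopy texture: per-pixel multiplicative luminance noise plus a
        # mid-frequency blotch field modulating clump brightness
        hf = rng.standard_normal((h, w))
        blotch = _low_frequency_field(rng, h, w, 12)
        lum = 1.0 + region.amplitude * hf + 0.6 * region.amplitude * blotch
        block *= np.clip(lum, 0.05, None)[:, :, None]
        if cat == "shadow_vegetation":
            shade = rng.uniform(0.3, 0.6)
            block *= shade
    elif cat == "artificial_green":
        hf = rng.standard_normal((h, w))
        block *= (1.0 + region.amplitude * hf)[:, :, None]

    return np.clip(block, 0.0, 1.0)


def generate_scene(spec: SceneSpec) -> SceneFixture:
    """Render a :class:`SceneSpec` into an image and its greenery mask.

    Deterministic for a fixed spec (seed included): regions are rendered
    in list order from a single seeded generator, later regions
    overwriting earlier ones in both image and mask.  The image is
    composited in float and quantized to 8 bits once at the end; the mask
    comes from region geometry alone.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.full((spec.height, spec.width, 3), 0.5, dtype=np.float64)
    mask = np.zeros((spec.height, spec.width), dtype=bool)

    for region in spec.regions:
        x0, y0, x1, y1 = region.box
        canvas[y0:y1, x0:x1] = _render_region(region, y1 - y0, x1 - x0, rng)
        mask[y0:y1, x0:x1] = region.is_greenery

    image = np.clip(np.rint(canvas * 255.0), 0, 255).astype(np.uint8)
    return SceneFixture(image=image, mask=mask, spec=spec)


def category_mask(fixture: SceneFixture, category: str) -> np.ndarray:
    """Boolean mask of pixels whose *visible* (top-most) region has the
    given category, honoring the same overwrite order as rendering."""
    if category not in CATEGORIES:
        raise InputError(f"unknown category {category!r}")
    out = np.zeros(fixture.mask.shape, dtype=bool)
    for region in fixture.spec.regions:
        x0, y0, x1, y1 = region.box
        out[y0:y1, x0:x1] = region.category == category
    return out


def mask_to_grid_labels(
    mask: np.ndarray, cell_px: int = 32, occupancy_threshold: float = 0.5
) -> np.ndarray:
    """Reduce a per-pixel boolean mask to per-cell occupancy labels.

    The mask is tiled into non-overlapping ``cell_px`` squares from the
    top-left corner (trailing remainder truncated); a cell is positive
    iff its greenery pixel fraction *strictly* exceeds
    ``occupancy_threshold`` — "more than a half" at the default 0.5, so a
    cell exactly half covered is negative.
    """
    if cell_px <= 0:
        raise InputError(f"cell_px must be positive, got {cell_px}")
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    rows, cols = h // cell_px, w // cell_px
    if rows == 0 or cols == 0:
        raise InputError(
            f"mask {h}x{w} smaller than one {cell_px}px cell in some dimension"
        )
    trimmed = mask[: rows * cell_px, : cols * cell_px]
    cells = trimmed.reshape(rows, cell_px, cols, cell_px)
    frac = cells.mean(axis=(1, 3))
    return frac > occupancy_threshold


@dataclass(frozen=True)
class _RectDraft:
    x0: int
    y0: int
    x1: int
    y1: int
    label: bool


def scene_to_annotations(
    fixture: SceneFixture,
    n_positive: int,
    n_negative: int,
    min_side: int = 32,
    max_side: int = 160,
    purity: float = 0.9,
    seed: int = 0,
    max_attempts_per_rect: int = 500,
    image_id: str | None = None,
):
    """Derive rectangle annotations from a scene's ground-truth mask.

    Stands in for the human rater: rectangles are rejection-sampled until
    their greenery pixel fraction is ``>= purity`` (positives) or
    ``<= 1 - purity`` (negatives).  Deterministic per seed.  Raises
    :class:`GenerationError` naming the infeasible class when sampling
    fails within the attempt budget.

    Returns a list of :class:`greenview.chopper.RectAnnotation` carrying
    the fixture's image id (``spec.seed`` keyed as ``scene-<seed>``).
    """
    from .chopper import RectAnnotation

    rng = np.random.default_rng(seed)
    h, w = fixture.mask.shape
    if min_side > min(h, w):
        raise GenerationError(f"min_side {min_side} exceeds scene size {w}x{h}")
    max_side = min(max_side, h, w)
    if image_id is None:
        image_id = f"scene-{fixture.spec.seed}"
    integral = np.pad(fixture.mask.cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    def green_fraction(x0: int, y0: int, x1: int, y1: int) -> float:
        total = (
            integral[y1, x1] - integral[y0, x1] - integral[y1, x0] + integral[y0, x0]
        )
        return total / ((x1 - x0) * (y1 - y0))

    def sample(label: bool, want: int) -> list[RectAnnotation]:
        out: list[RectAnnotation] = []
        for _ in range(want):
            for _attempt in range(max_attempts_per_rect):
                side_w = int(rng.integers(min_side, max_side + 1))
                side_h = int(rng.integers(min_side, max_side + 1))
                x0 = int(rng.integers(0, w - side_w + 1))
                y0 = int(rng.integers(0, h - side_h + 1))
                frac = green_fraction(x0, y0, x0 + side_w, y0 + side_h)
                ok = frac >= purity if label else frac <= 1.0 - purity
                if ok:
                    out.append(
                        RectAnnotation(image_id, x0, y0, x0 + side_w, y0 + side_h, label)
                    )
                    break
            else:
                cls = "positive (greenery)" if label else "negative (background)"
                raise GenerationError(
                    f"could not sample a {cls} rectangle at purity {purity} "
                    f"after {max_attempts_per_rect} attempts"
                )
        return out

    return sample(True, n_positive) + sample(False, n_negative)


def random_street_scene(
    seed: int,
    width: int = 640,
    height: int = 640,
    n_vegetation: int = 3,
    n_artificial: int = 1,
    n_shadow: int = 1,
) -> SceneSpec:
    """Compose a plausible streetscape layout: sky band on top, building
    band, road at the bottom, then vegetation / shadow-vegetation /
    artificial-green patches scattered over it.  All placement is drawn
    from a generator seeded with ``seed``; the returned spec reuses the
    same seed so rendering is reproducible end to end."""
    rng = np.random.default_rng(seed)
    regions: list[RegionSpec] = []

    sky_h = int(height * rng.uniform(0.28, 0.40))
    road_y = int(height * rng.uniform(0.62, 0.72))
    regions.append(RegionSpec("sky", (0, 0, width, sky_h)))
    regions.append(RegionSpec("building", (0, sky_h, width, road_y)))
    regions.append(RegionSpec("road", (0, road_y, width, height)))

    def place(category: str, lo: int, hi: int, y_range: tuple[float, float]) -> None:
        side_w = int(rng.integers(lo, hi))
        side_h = int(rng.integers(lo, hi))
        x0 = int(rng.integers(0, max(1, width - side_w)))
        ymin = int(height * y_range[0])
        ymax = max(ymin + 1, int(height * y_range[1]) - side_h)
        y0 = int(rng.integers(ymin, max(ymin + 1, ymax)))
        y1 = min(y0 + side_h, height)
        regions.append(RegionSpec(category, (x0, y0, min(x0 + side_w, width), y1)))

    for _ in range(n_vegetation):
        place("vegetation", 140, 280, (0.10, 0.75))
    for _ in range(n_shadow):
        place("shadow_vegetation", 90, 170, (0.30, 0.80))
    for _ in range(n_artificial):
        place("artificial_green", 90, 190, (0.45, 0.95))

    return SceneSpec(width=width, height=height, regions=tuple(regions), seed=seed)


# ---------------------------------------------------------------------------
# disk I/O: PNG image + PNG mask + YAML sidecar


def write_fixture(fixture: SceneFixture, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write a fixture as ``<stem>.png`` (image), ``<stem>.mask.png``
    (0/255 mask) and ``<stem>.yaml`` (spec echo); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.png",
        "mask": out_dir / f"{stem}.mask.png",
        "spec": out_dir / f"{stem}.yaml",
    }
    Image.fromarray(fixture.image).save(paths["image"])
    Image.fromarray(fixture.mask.astype(np.uint8) * 255).save(paths["mask"])
    spec = fixture.spec
    doc = {
        "width": spec.width,
        "height": spec.height,
        "seed": spec.seed,
        "regions": [
            {
                "category": r.category,
                "box": list(r.box),
                "texture_amplitude": r.texture_amplitude,
                "base_color": list(r.base_color) if r.base_color else None,
            }
            for r in spec.regions
        ],
    }
    paths["spec"].write_text(yaml.safe_dump(doc, sort_keys=False))
    return paths


def read_spec(path: str | Path) -> SceneSpec:
    doc = yaml.safe_load(Path(path).read_text())
    regions = tuple(
        RegionSpec(
            category=r["category"],
            box=tuple(r["box"]),
            texture_amplitude=r.get("texture_amplitude"),
            base_color=tuple(r["base_color"]) if r.get("base_color") else None,
        )
        for r in doc["regions"]
    )
    return SceneSpec(
        width=doc["width"], height=doc["height"], regions=regions, seed=doc["seed"]
    )
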