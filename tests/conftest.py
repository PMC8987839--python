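import numpy as np
import pytest

import greenview as gv


@pytest.fixture(scope="session")
def street_fixture():
    """One rendered 640x640 streetscape with all six region categories."""
    return gv.generate_scene(gv.random_street_scene(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_color_tiles(n_per_class: int, patch_px: int, seed: int):
    """Trivially color-separable tiles: flat green (positive) vs flat
    gray (negative), with a whisper of noise so training is not literally
    degenerate."""
    r = np.random.default_rng(seed)
    green = np.full((n_per_class, patch_px, patch_px, 3), (0.2, 0.6, 0.2), np.float32)
    gray = np.full((n_per_class, patch_px, patch_px, 3), (0.5, 0.5, 0.5), np.float32)
    X = np.concatenate([green, gray])
    X += 0.01 * r.standard_normal(X.shape).astype(np.float32)
    y = np.r_[np.ones(n_per_class, bool), np.zeros(n_per_class, bool)]
    order = r.permutation(len(y))
    return np.clip(X[order], 0, 1), y[order]


def make_texture_tiles(n_per_class: int, patch_px: int, seed: int):
    """Tiles separable by texture only: both classes share the same mean
    green, but positives carry strong multiplicative luminance noise and
    negatives are near-flat (the artificial-green failure mode)."""
    r = np.random.default_rng(seed)
    base = np.array((0.18, 0.45, 0.15), np.float32)
    shape = (n_per_class, patch_px, patch_px, 1)
    textured = base * (1 + 0.25 * r.standard_normal(shape).astype(np.float32))
    flat = base * (1 + 0.015 * r.standard_normal(shape).astype(np.float32))
    X = np.clip(np.concatenate([textured, flat]), 0, 1)
    y = np.r_[np.ones(n_per_class, bool), np.zeros(n_per_class, bool)]
    order = r.permutation(len(y))
    return X[order], y[order]
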