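"""A compact convolutional network in NumPy for binary patch labels.

LeNet-class stack sized for 32x32 RGB tiles: two valid 3x3 convolution
blocks (ReLU + 2x2 max-pool each), one dense ReLU layer with inverted
dropout, and a 2-way softmax head, trained with minibatch Adam on
cross-entropy.  Convolutions run as im2col matrix products; everything is
float32 and driven by a single seeded generator, so training is
deterministic for a fixed seed and thread count.

This module is the numerical engine only — estimator plumbing (splits,
history, serialization policy) lives in :mod:`greenview.classifier`.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InputError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, OH*OW, k*k*C) view-copy of all valid kxk windows."""
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, (n, oh, ow, k, k, c), (s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return windows.reshape(n, oh * ow, k * k * c)


def _maxpool2(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
    """2x2 max-pool with odd trailing row/col cropped.

    Returns (pooled, crop of the input actually pooled, ph, pw)."""
    n, h, w, c = a.shape
    ph, pw = h // 2, w // 2
    crop = a[:, : ph * 2, : pw * 2, :]
    pooled = crop.reshape(n, ph, 2, pw, 2, c).max(axis=(2, 4))
    return pooled, crop, ph, pw


def _maxpool2_backward(
    crop: np.ndarray, pooled: np.ndarray, grad: np.ndarray, out_h: int, out_w: int
) -> np.ndarray:
    """Route pooled-gradient back to the (possibly cropped) input."""
    n, ph, pw, c = pooled.shape
    r = crop.reshape(n, ph, 2, pw, 2, c)
    mask = r == pooled[:, :, None, :, None, :]
    d = mask * grad[:, :, None, :, None, :]
    out = np.zeros((n, out_h, out_w, c), dtype=crop.dtype)
    out[:, : ph * 2, : pw * 2, :] = d.reshape(n, ph * 2, pw * 2, c)
    return out


class PatchNet:
    """Weights + forward/backward/Adam state for the fixed architecture."""

    def __init__(
        self,
        patch_px: int = 32,
        channels: int = 3,
        conv_filters: tuple[int, int] = (32, 64),
        dense_units: int = 128,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        self.patch_px = patch_px
        self.channels = channels
        self.f1, self.f2 = conv_filters
        self.dense_units = dense_units
        self.dropout = dropout
        self.rng = rng if rng is not None else np.random.default_rng(0)

        # spatial sizes through the stack (valid conv 3, pool 2 with crop)
        self.c1 = patch_px - 2
        self.p1 = self.c1 // 2
        self.c2 = self.p1 - 2
        self.p2 = self.c2 // 2
        if self.p2 < 1:
            raise InputError(f"patch_px {patch_px} too small for the network")

        def he(shape, fan_in):
            return (self.rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )

        k1 = 9 * channels
        k2 = 9 * self.f1
        flat = self.p2 * self.p2 * self.f2
        self.params = {
            "W1": he((k1, self.f1), k1),
            "b1": np.zeros(self.f1, np.float32),
            "W2": he((k2, self.f2), k2),
            "b2": np.zeros(self.f2, np.float32),
            "W3": he((flat, dense_units), flat),
            "b3": np.zeros(dense_units, np.float32),
            "W4": he((dense_units, 2), dense_units),
            "b4": np.zeros(2, np.float32),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, dict]:
        p = self.params
        n = x.shape[0]
        x = np.ascontiguousarray(x, dtype=np.float32)

        col1 = _im2col(x, 3)
        z1 = col1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0).reshape(n, self.c1, self.c1, self.f1)
        pool1, crop1, _, _ = _maxpool2(a1)

        col2 = _im2col(pool1, 3)
        z2 = col2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0).reshape(n, self.c2, self.c2, self.f2)
        pool2, crop2, _, _ = _maxpool2(a2)

        flat = pool2.reshape(n, -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        if train and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            drop = (self.rng.random(a3.shape) < keep).astype(np.float32) / keep
            a3d = a3 * drop
        else:
            drop = None
            a3d = a3

        logits = a3d @ p["W4"] + p["b4"]
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        prob = expl / expl.sum(axis=1, keepdims=True)

        cache = dict(
            x=x, col1=col1, z1=z1, a1=a1, pool1=pool1, crop1=crop1,
            col2=col2, z2=z2, a2=a2, pool2=pool2, crop2=crop2,
            flat=flat, z3=z3, a3=a3, drop=drop, a3d=a3d, prob=prob,
        )
        return prob, cache

    def predict_proba(self, x: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Greenery-class probability column pair, computed in chunks."""
        out = np.empty((x.shape[0], 2), dtype=np.float32)
        for i in range(0, x.shape[0], chunk):
            out[i : i + chunk] = self.forward(x[i : i + chunk])[0]
        return out

    # -- backward ----------------------------------------------------------

    def backward(
        self, cache: dict, y: np.ndarray, sample_weight: np.ndarray | None = None
    ) -> dict:
        p = self.params
        n = y.shape[0]
        g: dict[str, np.ndarray] = {}

        dlogits = cache["prob"].copy()
        dlogits[np.arange(n), y] -= 1.0
        if sample_weight is not None:
            dlogits *= sample_weight[:, None] / sample_weight.sum()
        else:
            dlogits /= n

        g["W4"] = cache["a3d"].T @ dlogits
        g["b4"] = dlogits.sum(0)
        da3 = dlogits @ p["W4"].T
        if cache["drop"] is not None:
            da3 = da3 * cache["drop"]
        dz3 = da3 * (cache["z3"] > 0)
        g["W3"] = cache["flat"].T @ dz3
        g["b3"] = dz3.sum(0)

        dpool2 = (dz3 @ p["W3"].T).reshape(cache["pool2"].shape)
        da2 = _maxpool2_backward(
            cache["crop2"], cache["pool2"], dpool2, self.c2, self.c2
        )
        dz2 = da2.reshape(n, self.c2 * self.c2, self.f2) * (cache["z2"] > 0)
        g["W2"] = np.einsum("nij,nik->jk", cache["col2"], dz2)
        g["b2"] = dz2.sum((0, 1))

        # fold conv2's column gradient back onto pool1's pixels
        dcol2 = dz2 @ p["W2"].T
        dpool1 = np.zeros_like(cache["pool1"])
        dcol2 = dcol2.reshape(n, self.c2, self.c2, 3, 3, self.f1)
        for i in range(3):
            for j in range(3):
                dpool1[:, i : i + self.c2, j : j + self.c2, :] += dcol2[:, :, :, i, j, :]

        da1 = _maxpool2_backward(
            cache["crop1"], cache["pool1"], dpool1, self.c1, self.c1
        )
        dz1 = da1.reshape(n, self.c1 * self.c1, self.f1) * (cache["z1"] > 0)
        g["W1"] = np.einsum("nij,nik->jk", cache["col1"], dz1)
        g["b1"] = dz1.sum((0, 1))
        return g

    def adam_step(
        self,
        grads: dict,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, param in self.params.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * grads[k]
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * grads[k] ** 2
            mh = m / (1 - beta1**t)
            vh = v / (1 - beta2**t)
            param -= (lr * mh / (np.sqrt(vh) + eps)).astype(np.float32)

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            if k not in state:
                raise InputError(f"missing weight {k!r} in state dict")
            if state[k].shape != self.params[k].shape:
                raise InputError(
                    f"weight {k!r} has shape {state[k].shape}, "
                    f"expected {self.params[k].shape}"
                )
            self.params[k] = np.asarray(state[k], dtype=np.float32).copy()


def cross_entropy(prob: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    return float(-np.log(np.clip(prob[np.arange(len(y)), y], eps, None)).mean())
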