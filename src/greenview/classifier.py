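"""The binary greenery patch classifier, as a scikit-learn estimator.

:class:`PatchCNNClassifier` wraps the NumPy convolutional network from
:mod:`greenview.nn` behind the standard ``fit`` / ``predict`` /
``predict_proba`` surface, so it composes with sklearn pipelines and
model selection.  Training follows the survey protocol's regime: Adam at
its published default learning rate, minibatches of 32, a stratified
20% validation split, 30 epochs, with per-epoch accuracy and loss
recorded in ``history_``.

``X`` may be ``(n, p, p, 3)`` tiles or the same tiles flattened to
``(n, 3*p*p)`` (the sklearn-native 2-D layout); values are expected in
[0, 1] (uint8 input is rescaled).  ``predict`` applies a configurable
decision threshold (default 0.5) to the greenery probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .chopper import Patch, PatchSet
from .exceptions import InputError
from .nn import PatchNet, cross_entropy

#: Adam's published default step size, used when learning_rate is None.
ADAM_DEFAULT_LR = 1e-3


@dataclass
class TrainingHistory:
    """Per-epoch training curves (train metrics are minibatch averages
    over the epoch, validation metrics full-split passes)."""

    accuracy: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.accuracy)

    def to_dict(self) -> dict[str, list[float]]:
        return {
            "accuracy": self.accuracy,
            "loss": self.loss,
            "val_accuracy": self.val_accuracy,
            "val_loss": self.val_loss,
        }


class PatchCNNClassifier(ClassifierMixin, BaseEstimator):
    """Small convolutional network classifying square RGB patches as
    greenery vs. everything else.

    Parameters
    ----------
    patch_px : side length of the square input tiles.
    epochs, batch_size : minibatch training regime.
    validation_fraction : stratified held-out fraction tracked per epoch.
    learning_rate : Adam step size; ``None`` means Adam's default (1e-3).
    conv_filters, dense_units, dropout : architecture knobs — two 3x3
        convolution blocks with these filter counts, then one dense ReLU
        layer with inverted dropout, then a 2-way softmax.
    decision_threshold : greenery probability at or above which
        ``predict`` returns the positive class.
    class_weight : ``None`` (no reweighting, the default) or
        ``"balanced"`` to weight samples inversely to class frequency.
    random_state : seeds weight init, the split, shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of the two class labels, sorted.
    history_ : :class:`TrainingHistory` with one entry per epoch run.
    n_features_in_ : flattened input dimensionality (3 * patch_px**2).
    """

    def __init__(
        self,
        patch_px: int = 32,
        epochs: int = 30,
        batch_size: int = 32,
        validation_fraction: float = 0.2,
        learning_rate: float | None = None,
        conv_filters: tuple[int, int] = (32, 64),
        dense_units: int = 128,
        dropout: float = 0.5,
        decision_threshold: float = 0.5,
        class_weight: str | None = None,
        random_state: int = 0,
    ):
        self.patch_px = patch_px
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.learning_rate = learning_rate
        self.conv_filters = conv_filters
        self.dense_units = dense_units
        self.dropout = dropout
        self.decision_threshold = decision_threshold
        self.class_weight = class_weight
        self.random_state = random_state

    # -- input handling ----------------------------------------------------

    def _check_config(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise InputError(
                f"validation_fraction must lie in (0, 1), got {self.validation_fraction}"
            )
        if not (0.0 < self.decision_threshold < 1.0):
            raise InputError(
                f"decision_threshold must lie in (0, 1), got {self.decision_threshold}"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise InputError("epochs and batch_size must be positive")

    def _as_tiles(self, X) -> np.ndarray:
        X = np.asarray(X)
        p = self.patch_px
        if X.ndim == 2:
            if X.shape[1] != 3 * p * p:
                raise InputError(
                    f"flattened input has {X.shape[1]} features; "
                    f"expected {3 * p * p} for {p}x{p} RGB tiles"
                )
            X = X.reshape(-1, p, p, 3)
        if X.ndim != 4 or X.shape[1:] != (p, p, 3):
            raise InputError(
                f"expected (n, {p}, {p}, 3) tiles, got shape {X.shape}"
            )
        if X.dtype == np.uint8:
            X = X.astype(np.float32) / 255.0
        return np.ascontiguousarray(X, dtype=np.float32)

    # -- estimator surface -------------------------------------------------

    def fit(self, X, y) -> "PatchCNNClassifier":
        self._check_config()
        X = self._as_tiles(X)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise InputError("cannot train on an empty patch set")
        if X.shape[0] != y.shape[0]:
            raise InputError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise InputError(
                f"need exactly two classes, got {list(self.classes_)}; "
                "single-class patch sets cannot train a discriminator"
            )
        y_idx = np.searchsorted(self.classes_, y).astype(np.int64)

        rng = np.random.default_rng(self.random_state)
        X_tr, X_val, y_tr, y_val = train_test_split(
            X,
            y_idx,
            test_size=self.validation_fraction,
            stratify=y_idx,
            random_state=int(rng.integers(2**31 - 1)),
        )
        if min(len(X_tr), len(X_val)) < 1:
            raise InputError("validation split left an empty partition")

        net = PatchNet(
            patch_px=self.patch_px,
            conv_filters=tuple(self.conv_filters),
            dense_units=self.dense_units,
            dropout=self.dropout,
            rng=rng,
        )
        lr = ADAM_DEFAULT_LR if self.learning_rate is None else self.learning_rate

        weights = None
        if self.class_weight == "balanced":
            counts = np.bincount(y_tr, minlength=2)
            weights = (len(y_tr) / (2.0 * counts)).astype(np.float32)
        elif self.class_weight is not None:
            raise InputError(f"unsupported class_weight {self.class_weight!r}")

        history = TrainingHistory()
        n_tr = len(X_tr)
        for _epoch in range(self.epochs):
            order = rng.permutation(n_tr)
            epoch_loss, epoch_hits, seen = 0.0, 0, 0
            for start in range(0, n_tr, self.batch_size):
                idx = order[start : start + self.batch_size]
                prob, cache = net.forward(X_tr[idx], train=True)
                sw = weights[y_tr[idx]] if weights is not None else None
                grads = net.backward(cache, y_tr[idx], sample_weight=sw)
                net.adam_step(grads, lr=lr)
                epoch_loss += cross_entropy(prob, y_tr[idx]) * len(idx)
                epoch_hits += int((prob.argmax(1) == y_tr[idx]).sum())
                seen += len(idx)
            val_prob = net.predict_proba(X_val)
            history.loss.append(epoch_loss / seen)
            history.accuracy.append(epoch_hits / seen)
            history.val_loss.append(cross_entropy(val_prob, y_val))
            history.val_accuracy.append(float((val_prob.argmax(1) == y_val).mean()))

        self.net_ = net
        self.history_ = history
        self.n_features_in_ = 3 * self.patch_px**2
        self.learning_rate_ = lr
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability matrix with columns ordered as ``classes_``."""
        check_is_fitted(self, "net_")
        X = self._as_tiles(X)
        if X.shape[0] == 0:
            return np.empty((0, 2), dtype=np.float32)
        return self.net_.predict_proba(X)

    def greenery_probability(self, X) -> np.ndarray:
        """Probability of the positive (greenery) class per tile."""
        return self.predict_proba(X)[:, int(np.argmax(self.classes_))]

    def predict(self, X) -> np.ndarray:
        prob = self.predict_proba(X)
        pos_col = int(np.argmax(self.classes_))
        positive = prob[:, pos_col] >= self.decision_threshold
        return np.where(positive, self.classes_[pos_col], self.classes_[1 - pos_col])

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (``<path>``, NumPy .npz) plus a JSON sidecar
        (``<path>.json``) echoing the configuration and final metrics."""
        check_is_fitted(self, "net_")
        path = Path(path)
        np.savez(path, classes=self.classes_, **self.net_.state_dict())
        sidecar = {
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "learning_rate_used": self.learning_rate_,
            "history": self.history_.to_dict(),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNNClassifier":
        path = Path(path)
        npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
        if not npz_path.exists():
            npz_path = path
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        params = dict(sidecar["params"])
        if isinstance(params.get("conv_filters"), list):
            params["conv_filters"] = tuple(params["conv_filters"])
        est = cls(**params)
        with np.load(npz_path) as data:
            est.classes_ = data["classes"]
            state = {k: data[k] for k in data.files if k != "classes"}
        est.net_ = PatchNet(
            patch_px=est.patch_px,
            conv_filters=tuple(est.conv_filters),
            dense_units=est.dense_units,
            dropout=est.dropout,
            rng=np.random.default_rng(est.random_state),
        )
        est.net_.load_state_dict(state)
        est.history_ = TrainingHistory(**sidecar["history"])
        est.n_features_in_ = 3 * est.patch_px**2
        est.learning_rate_ = sidecar["learning_rate_used"]
        return est


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator


def train(
    patchset: PatchSet, **config
) -> tuple[PatchCNNClassifier, TrainingHistory]:
    """Fit a :class:`PatchCNNClassifier` on a chopped patch set."""
    X, y = patchset.arrays()
    est = PatchCNNClassifier(**config).fit(X, y)
    return est, est.history_


def predict_patches(
    model: PatchCNNClassifier, patches: Sequence[Patch]
) -> np.ndarray:
    """Greenery probability for each patch, order-preserving."""
    if len(patches) == 0:
        return np.empty(0, dtype=np.float32)
    X = np.stack([p.pixels for p in patches])
    return model.greenery_probability(X)
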