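"""Cell-wise evaluation of predicted grids against reference grids.

Predictions and references are paired by image id, compared cell by cell
at matching positions, pooled into one confusion table, and summarized as
overall accuracy, precision and recall.  The reference may come from a
human rater applying the strict-majority occupancy rule, or — on
synthetic scenes — from the ground-truth mask put through the same rule.

Undefined ratios (empty denominators) are surfaced as ``None``, never
silently coerced to 0, so degenerate synthetic cases cannot corrupt a
comparison unnoticed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InputError, PairingError
from .grid import GridClassification


@dataclass(frozen=True)
class ReferenceGrid:
    """Rater (or ground-truth) cell labels for one image."""

    image_id: str
    cell_labels: np.ndarray  # (rows, cols) bool

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cell_labels", np.asarray(self.cell_labels, dtype=bool)
        )
        if self.cell_labels.ndim != 2:
            raise InputError("reference cell labels must be a 2-D grid")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalMetrics:
    """``precision`` / ``recall`` are ``None`` when their denominator is
    empty (no predicted / no actual positives)."""

    overall_accuracy: float
    precision: float | None
    recall: float | None


def confusion(
    predictions: Sequence[GridClassification],
    references: Sequence[ReferenceGrid],
) -> ConfusionCounts:
    """Pool position-wise cell agreement over all paired images."""
    ref_by_id: dict[str, ReferenceGrid] = {}
    for ref in references:
        if ref.image_id in ref_by_id:
            raise PairingError(f"duplicate reference for image {ref.image_id!r}")
        ref_by_id[ref.image_id] = ref

    seen = set()
    tp = fp = fn = tn = 0
    for pred in predictions:
        if pred.image_id in seen:
            raise PairingError(f"duplicate prediction for image {pred.image_id!r}")
        seen.add(pred.image_id)
        ref = ref_by_id.pop(pred.image_id, None)
        if ref is None:
            raise PairingError(f"no reference grid for image {pred.image_id!r}")
        if ref.cell_labels.shape != pred.cell_mask.shape:
            raise PairingError(
                f"shape mismatch on image {pred.image_id!r}: prediction "
                f"{pred.cell_mask.shape} vs reference {ref.cell_labels.shape}"
            )
        p, r = pred.cell_mask, ref.cell_labels
        tp += int((p & r).sum())
        fp += int((p & ~r).sum())
        fn += int((~p & r).sum())
        tn += int((~p & ~r).sum())
    if ref_by_id:
        raise PairingError(
            f"references without predictions: {sorted(ref_by_id)}"
        )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(counts: ConfusionCounts) -> EvalMetrics:
    """accuracy = (tp+tn)/N, precision = tp/(tp+fp), recall = tp/(tp+fn)."""
    if counts.total == 0:
        raise InputError("cannot compute metrics over zero cells")
    precision = (
        counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    )
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    return EvalMetrics(
        overall_accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        recall=recall,
    )


def evaluate(
    predictions: Sequence[GridClassification],
    references: Sequence[ReferenceGrid],
) -> tuple[ConfusionCounts, EvalMetrics]:
    counts = confusion(predictions, references)
    return counts, metrics(counts)
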