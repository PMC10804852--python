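"""Multi-class evaluation: confusion matrix, accuracy, precision, recall, F1.

The confusion matrix carries one extra predicted-class column for the
voting strategy's INVALID outcomes; an invalid vote is never correct and
never contributes to any real class's predicted count.

Precision and recall are macro-averaged by default (per-class values
averaged unweighted), which makes recall coincide with accuracy on
class-balanced test sets; micro and support-weighted averaging are
available via the ``average`` argument.  All metrics are reported as
percentages in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .fusion import INVALID

__all__ = ["ConfusionMatrix", "confusion_matrix", "classification_metrics"]


@dataclass
class ConfusionMatrix:
    """k × (k+1) count matrix: true class (rows) × predicted class + INVALID."""

    counts: np.ndarray
    class_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_ids)
        if self.counts.shape != (k, k + 1):
            raise InvalidInputError(
                f"counts must have shape ({k}, {k + 1}), got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise InvalidInputError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def invalid_count(self) -> int:
        return int(self.counts[:, -1].sum())

    @property
    def square(self) -> np.ndarray:
        """The k × k block over real predicted classes (INVALID column dropped)."""
        return self.counts[:, :-1]


def confusion_matrix(
    truth: Sequence[str],
    predicted: Sequence[str],
    class_ids: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Tally aligned (truth, predicted) label pairs into a ConfusionMatrix.

    ``class_ids`` fixes the class ordering; by default classes are ordered
    by first appearance in ``truth``.  Predictions equal to the INVALID
    sentinel land in the extra final column.
    """
    truth = [str(x) for x in truth]
    predicted = [str(x) for x in predicted]
    if len(truth) != len(predicted):
        raise InvalidInputError(
            f"{len(truth)} truth labels vs {len(predicted)} predictions"
        )
    if class_ids is None:
        seen: dict[str, None] = {}
        for lab in truth:
            seen.setdefault(lab, None)
        class_ids = tuple(seen)
    else:
        class_ids = tuple(str(c) for c in class_ids)
    index = {c: i for i, c in enumerate(class_ids)}
    k = len(class_ids)
    counts = np.zeros((k, k + 1), dtype=int)
    for t_lab, p_lab in zip(truth, predicted):
        if t_lab not in index:
            raise InvalidInputError(f"unknown true label {t_lab!r}")
        if p_lab == INVALID:
            counts[index[t_lab], k] += 1
        elif p_lab in index:
            counts[index[t_lab], index[p_lab]] += 1
        else:
            raise InvalidInputError(f"unknown predicted label {p_lab!r}")
    return ConfusionMatrix(counts, class_ids)


def classification_metrics(cm: ConfusionMatrix, average: str = "macro") -> dict:
    """Accuracy, precision, recall and F1 (percentages) from a confusion matrix.

    Per-class precision is ``diag / column sum`` over the real predicted
    columns (a class nobody predicted scores precision 0), per-class recall
    is ``diag / row sum``.  The headline precision/recall are the chosen
    average of the per-class values; F1 is the harmonic mean of that
    precision/recall pair.
    """
    if cm.total == 0:
        raise InvalidInputError("cannot compute metrics for an empty confusion matrix")
    if average not in ("macro", "micro", "weighted"):
        raise InvalidInputError(f"unknown averaging scheme {average!r}")
    sq = cm.square.astype(float)
    diag = np.diag(sq)
    row_sums = cm.counts.sum(axis=1).astype(float)  # includes INVALID predictions
    col_sums = sq.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(col_sums > 0, diag / np.where(col_sums > 0, col_sums, 1), 0.0)
        rec_c = np.where(row_sums > 0, diag / np.where(row_sums > 0, row_sums, 1), 0.0)

    accuracy = diag.sum() / cm.total
    if average == "macro":
        precision = float(prec_c.mean())
        recall = float(rec_c.mean())
    elif average == "weighted":
        support = row_sums / row_sums.sum()
        precision = float((prec_c * support).sum())
        recall = float((rec_c * support).sum())
    else:  # micro
        predicted_total = col_sums.sum()
        precision = float(diag.sum() / predicted_total) if predicted_total > 0 else 0.0
        recall = float(diag.sum() / row_sums.sum())
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)

    return {
        "accuracy": 100.0 * accuracy,
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "f1": 100.0 * f1,
        "average": average,
        "invalid_count": cm.invalid_count,
        "per_class": {
            c: {"precision": 100.0 * float(prec_c[i]), "recall": 100.0 * float(rec_c[i])}
            for i, c in enumerate(cm.class_ids)
        },
    }
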