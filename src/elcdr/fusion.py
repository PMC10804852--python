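"""Fusion strategies: separability-weighted, average, and majority voting.

Each member model emits a per-sample softmax row ``(s_1 … s_k)``.  The
weighted strategy fuses them as ``sf_final = sum_i w_i * sf_i`` with the
weights from :mod:`elcdr.separation`; average weighting is the uniform
special case ``w_i = 1/n``; majority voting lets each model vote for its
argmax class and requires a strict plurality — when the top vote count is
shared by two or more classes (including the all-distinct case) the vote
is invalid and the sample gets the :data:`INVALID` sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, InvalidInputError
from .separation import WeightVector

__all__ = [
    "INVALID",
    "SoftmaxTable",
    "EnsembleResult",
    "predict_argmax",
    "fuse_weighted",
    "fuse_average",
    "fuse_voting",
]

#: Sentinel prediction for a sample on which voting reaches no strict plurality.
INVALID = "INVALID"

_ROW_SUM_TOL = 1e-6


@dataclass
class SoftmaxTable:
    """``s`` samples × ``k`` class probabilities emitted by one model."""

    probs: np.ndarray
    sample_ids: tuple[str, ...]
    class_ids: tuple[str, ...]
    model_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.class_ids = tuple(str(c) for c in self.class_ids)
        if self.probs.ndim != 2:
            raise InvalidInputError("softmax probabilities must be a 2-D (s, k) array")
        s, k = self.probs.shape
        if len(self.sample_ids) != s:
            raise InvalidInputError(f"{len(self.sample_ids)} sample ids for {s} rows")
        if len(self.class_ids) != k:
            raise InvalidInputError(f"{len(self.class_ids)} class ids for {k} columns")
        if not np.isfinite(self.probs).all():
            raise InvalidInputError("softmax table contains non-finite entries")
        if (self.probs < -_ROW_SUM_TOL).any() or (self.probs > 1 + _ROW_SUM_TOL).any():
            raise InvalidInputError("softmax entries must lie in [0, 1]")
        bad = np.abs(self.probs.sum(axis=1) - 1.0) > _ROW_SUM_TOL
        if bad.any():
            i = int(np.argmax(bad))
            raise InvalidInputError(
                f"softmax row for sample {self.sample_ids[i]!r} sums to "
                f"{self.probs[i].sum():.6g}, not 1 (tolerance {_ROW_SUM_TOL})"
            )

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def k(self) -> int:
        return self.probs.shape[1]


@dataclass
class EnsembleResult:
    """Fused per-sample probabilities plus the predicted class per sample.

    For voting, ``fused`` holds the vote-share distribution (votes / n) so
    the result type is uniform across strategies, and ``predicted`` may
    contain the :data:`INVALID` sentinel.
    """

    fused: np.ndarray
    predicted: tuple[str, ...]
    sample_ids: tuple[str, ...]
    class_ids: tuple[str, ...]
    strategy: str


def predict_argmax(row: Sequence[float], class_ids: Sequence[str]) -> str:
    """Class with the maximum probability; ties break to the lowest class index."""
    row = np.asarray(row, dtype=float)
    if row.size == 0:
        raise InvalidInputError("cannot take the argmax of an empty probability row")
    if row.size != len(class_ids):
        raise InvalidInputError(f"{row.size} probabilities for {len(class_ids)} classes")
    if not np.isfinite(row).all():
        raise InvalidInputError("probability row contains non-finite entries")
    return str(class_ids[int(np.argmax(row))])


def _check_aligned(tables: Sequence[SoftmaxTable]) -> None:
    if len(tables) == 0:
        raise InvalidInputError("need at least one softmax table")
    ref = tables[0]
    for tab in tables[1:]:
        if tab.class_ids != ref.class_ids:
            bad = next(
                (a for a, b in zip(tab.class_ids, ref.class_ids) if a != b),
                f"k={tab.k} vs k={ref.k}",
            )
            raise AlignmentError(
                f"class ids of model {tab.model_id!r} do not match model "
                f"{ref.model_id!r}: first mismatch {bad!r}"
            )
        if tab.sample_ids != ref.sample_ids:
            bad = next(
                (a for a, b in zip(tab.sample_ids, ref.sample_ids) if a != b),
                f"s={tab.n_samples} vs s={ref.n_samples}",
            )
            raise AlignmentError(
                f"sample ids of model {tab.model_id!r} do not match model "
                f"{ref.model_id!r}: first mismatch {bad!r}"
            )


def fuse_weighted(tables: Sequence[SoftmaxTable], weights: WeightVector) -> EnsembleResult:
    """Weighted softmax fusion: fused row = sum_i w_i * row_i."""
    _check_aligned(tables)
    if len(weights) != len(tables):
        raise InvalidInputError(f"{len(weights)} weights for {len(tables)} tables")
    ref = tables[0]
    fused = np.zeros_like(ref.probs)
    for w, tab in zip(weights.weights, tables):
        fused += w * tab.probs
    predicted = tuple(predict_argmax(row, ref.class_ids) for row in fused)
    return EnsembleResult(fused, predicted, ref.sample_ids, ref.class_ids, "elcdr")


def fuse_average(tables: Sequence[SoftmaxTable]) -> EnsembleResult:
    """Average weighting: uniform weights 1/n."""
    _check_aligned(tables)
    n = len(tables)
    fused = sum(tab.probs for tab in tables) / n
    ref = tables[0]
    predicted = tuple(predict_argmax(row, ref.class_ids) for row in fused)
    return EnsembleResult(fused, predicted, ref.sample_ids, ref.class_ids, "average")


def fuse_voting(
    tables: Sequence[SoftmaxTable], fallback: str | None = None
) -> EnsembleResult:
    """Majority voting with strict-plurality requirement.

    Each model votes for its argmax class.  A sample's prediction is the
    class with strictly more votes than any other; if the maximum vote
    count is shared (including every model voting differently) the
    prediction is :data:`INVALID` — unless ``fallback='average'``, which
    resolves such samples by average fusion instead.

    ``fused`` carries vote shares (votes / n) per class.
    """
    _check_aligned(tables)
    if fallback not in (None, "average"):
        raise InvalidInputError(f"unknown voting fallback {fallback!r}")
    ref = tables[0]
    n = len(tables)
    votes = np.zeros_like(ref.probs)
    for tab in tables:
        winners = np.argmax(tab.probs, axis=1)
        votes[np.arange(ref.n_samples), winners] += 1.0
    shares = votes / n
    avg = fuse_average(tables) if fallback == "average" else None
    predicted = []
    for i, counts in enumerate(votes):
        top = counts.max()
        if (counts == top).sum() == 1:
            predicted.append(str(ref.class_ids[int(np.argmax(counts))]))
        elif avg is not None:
            predicted.append(avg.predicted[i])
        else:
            predicted.append(INVALID)
    return EnsembleResult(shares, tuple(predicted), ref.sample_ids, ref.class_ids, "voting")
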