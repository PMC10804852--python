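"""Class-separability geometry of a model's feature space.

A trained classifier embeds each training image as a feature vector (here,
any numeric vector table — how the vectors were produced is the caller's
business).  The quality of that embedding is summarised by three numbers:

``icD``
    in-category distance — the average Euclidean distance of every vector
    to its own class centroid (compactness of the clusters),
``bcD``
    between-categories distance — the average pairwise Euclidean distance
    among the class centroids (spread of the clusters),
``FEP``
    feature-extraction performance — the ratio ``bcD / icD``.  A model
    whose classes form tight, well-separated clusters scores high.

Ensemble weights are each model's FEP normalised over all models, so a
model with better-separated classes contributes more to the fused softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "FeatureVectorSet",
    "CentroidSet",
    "SeparationStats",
    "WeightVector",
    "euclidean_distance",
    "compute_centroids",
    "in_category_distance",
    "between_categories_distance",
    "feature_extraction_performance",
    "ensemble_weights",
]


def _unique_in_order(labels: Sequence[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab, None)
    return tuple(seen)


@dataclass
class FeatureVectorSet:
    """``t`` labeled feature vectors of dimension ``d`` over ``k`` classes.

    Parameters
    ----------
    vectors : (t, d) float array
        Embedding coordinates, one row per training sample.
    labels : sequence of str, length t
        Class identifier of each sample.
    class_ids : tuple of str, optional
        Explicit class ordering.  Defaults to order of first appearance
        in ``labels``.  All outputs report class identifiers, never bare
        ordinals.
    model_id : str
        Identifier of the model this feature space belongs to.
    sample_ids : sequence of str, optional
        Per-sample identifiers; generated as ``s0001…`` when omitted.
    """

    vectors: np.ndarray
    labels: np.ndarray
    class_ids: tuple[str, ...] = ()
    model_id: str = ""
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise InvalidInputError(
                f"vectors must be a 2-D (t, d) array, got ndim={self.vectors.ndim}"
            )
        t, d = self.vectors.shape
        if d < 1 or t < 1:
            raise InvalidInputError(f"need t >= 1 samples and d >= 1 features, got t={t}, d={d}")
        if not np.isfinite(self.vectors).all():
            raise InvalidInputError("feature vectors contain non-finite components")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (t,):
            raise InvalidInputError(
                f"labels length {self.labels.shape[0] if self.labels.ndim == 1 else self.labels.shape} "
                f"does not match vector count {t}"
            )
        observed = _unique_in_order(self.labels)
        if not self.class_ids:
            self.class_ids = observed
        else:
            self.class_ids = tuple(str(c) for c in self.class_ids)
            missing = set(observed) - set(self.class_ids)
            if missing:
                raise InvalidInputError(f"labels contain classes not in class_ids: {sorted(missing)}")
        if len(self.class_ids) < 2:
            raise InvalidInputError(f"need at least 2 classes, got {len(self.class_ids)}")
        for cid in self.class_ids:
            if not np.any(self.labels == cid):
                raise InvalidInputError(f"class {cid!r} has no member vectors")
        if not self.sample_ids:
            width = max(4, len(str(t)))
            self.sample_ids = tuple(f"s{i + 1:0{width}d}" for i in range(t))
        else:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
            if len(self.sample_ids) != t:
                raise InvalidInputError(
                    f"sample_ids length {len(self.sample_ids)} does not match vector count {t}"
                )

    @property
    def t(self) -> int:
        return self.vectors.shape[0]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    @property
    def k(self) -> int:
        return len(self.class_ids)

    def class_index(self, class_id: str) -> int:
        return self.class_ids.index(class_id)

    def members(self, class_id: str) -> np.ndarray:
        """Row view of the vectors belonging to one class."""
        return self.vectors[self.labels == class_id]


@dataclass
class CentroidSet:
    """One centroid (class mean vector) per class, ordered as ``class_ids``."""

    centroids: np.ndarray
    class_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] != len(self.class_ids):
            raise InvalidInputError("centroids must be a (k, d) array matching class_ids")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def d(self) -> int:
        return self.centroids.shape[1]


@dataclass(frozen=True)
class SeparationStats:
    """(icD, bcD, FEP) summary of one model's feature-space geometry."""

    icd: float
    bcd: float
    fep: float


@dataclass
class WeightVector:
    """Normalised ensemble weights, one per model, summing to 1."""

    weights: np.ndarray
    model_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or len(self.weights) != len(self.model_ids):
            raise InvalidInputError("weights must be 1-D and match model_ids")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise InvalidInputError(f"weights must sum to 1, got {self.weights.sum()!r}")

    def __len__(self) -> int:
        return len(self.weights)

    def as_dict(self) -> dict[str, float]:
        return {m: float(w) for m, w in zip(self.model_ids, self.weights)}


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two vectors of equal dimension."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(
            f"dimension mismatch: {a.shape} vs {b.shape}"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InvalidInputError("vectors contain non-finite components")
    return float(np.linalg.norm(a - b))


def compute_centroids(fvs: FeatureVectorSet) -> CentroidSet:
    """Per-class centroids: the component-wise mean of each class's vectors."""
    cents = np.empty((fvs.k, fvs.d), dtype=float)
    for p, cid in enumerate(fvs.class_ids):
        cents[p] = fvs.members(cid).mean(axis=0)
    return CentroidSet(cents, fvs.class_ids)


def in_category_distance(fvs: FeatureVectorSet, cents: CentroidSet | None = None) -> float:
    """Mean distance of every vector to its own class centroid (icD)."""
    if cents is None:
        cents = compute_centroids(fvs)
    if cents.class_ids != fvs.class_ids or cents.d != fvs.d:
        raise InvalidInputError("centroid set does not match the feature-vector set")
    total = 0.0
    for p, cid in enumerate(fvs.class_ids):
        total += float(np.linalg.norm(fvs.members(cid) - cents.centroids[p], axis=1).sum())
    return total / fvs.t


def between_categories_distance(cents: CentroidSet) -> float:
    """Mean Euclidean distance over all k(k-1)/2 unordered centroid pairs (bcD)."""
    if cents.k < 2:
        raise InvalidInputError(
            f"between-categories distance undefined for k={cents.k} (need k >= 2)"
        )
    return float(pdist(cents.centroids).mean())


def feature_extraction_performance(
    fvs: FeatureVectorSet, icd_epsilon: float | None = None
) -> SeparationStats:
    """icD, bcD and their ratio FEP = bcD / icD for one feature space.

    ``icd_epsilon``, if given, clamps a vanishing icD to that floor instead
    of raising :class:`DegenerateGeometryError`; by default perfectly
    collapsed clusters are an error, because a silent infinity would
    corrupt weight normalisation downstream.
    """
    cents = compute_centroids(fvs)
    icd = in_category_distance(fvs, cents)
    bcd = between_categories_distance(cents)
    if icd <= 0.0:
        if icd_epsilon is not None and icd_epsilon > 0:
            icd = float(icd_epsilon)
        else:
            raise DegenerateGeometryError(
                "icD is zero: every vector coincides with its class centroid; "
                "FEP = bcD/icD is undefined (pass icd_epsilon to clamp)"
            )
    return SeparationStats(icd=icd, bcd=bcd, fep=bcd / icd)


def ensemble_weights(
    feps: Sequence[float], model_ids: Sequence[str] | None = None
) -> WeightVector:
    """Normalise per-model FEP scores into ensemble weights w_g = FEP_g / sum(FEP)."""
    feps = np.asarray(list(feps), dtype=float)
    if feps.size == 0:
        raise InvalidInputError("cannot compute weights for an empty model list")
    if not np.isfinite(feps).all() or (feps <= 0).any():
        raise InvalidInputError(f"all FEP values must be finite and > 0, got {feps.tolist()}")
    if model_ids is None:
        model_ids = tuple(f"model_{g + 1}" for g in range(feps.size))
    model_ids = tuple(str(m) for m in model_ids)
    if len(model_ids) != feps.size:
        raise InvalidInputError(
            f"{len(model_ids)} model ids for {feps.size} FEP values"
        )
    w = feps / feps.sum()
    # guard against accumulated rounding on long model lists
    w = w / w.sum()
    return WeightVector(w, model_ids)
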