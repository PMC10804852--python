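"""Synthetic multi-model ensembles for exercising the full pipeline.

Real use feeds the package feature vectors extracted from trained
convolutional networks.  This module stands in for that stage: each
simulated model gets its own feature space in which every class is an
isotropic Gaussian cluster.  The class means sit at distance
``separation`` from the origin along mutually orthogonal (when ``k <= d``)
random directions, so every pair of means is ``separation * sqrt(2)``
apart; samples scatter around them with standard deviation ``spread``.
Turning ``separation`` up therefore raises the between-class distance
while the within-class distance stays put — exactly the geometry the
separability weight rewards.

The matched classifier is a centroid-distance softmax: a test sample's
probability for class ``p`` is proportional to ``exp(-d(x, cen_p) / T)``
with temperature ``T``.  This ties classification quality to the same
geometry, so a model with better-separated clusters is also the more
accurate voter — the premise the ensemble-weighting scheme relies on.

Train and test splits are drawn independently from the same class means
(fresh draws, not a partition), keeping per-class counts exact.  The test
truth labels are shared across models: each model embeds "the same
samples" into its own space as an independent draw with the same label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .fusion import SoftmaxTable
from .separation import CentroidSet, FeatureVectorSet, compute_centroids

__all__ = [
    "ModelSpec",
    "SynthConfig",
    "generate_feature_space",
    "simulate_softmax",
    "generate_ensemble",
    "EnsembleData",
]


@dataclass(frozen=True)
class ModelSpec:
    """Geometry of one simulated model's feature space."""

    model_id: str
    separation: float  # distance of each class mean from the origin, >= 0
    spread: float  # within-class standard deviation, > 0
    temperature: float = 1.0  # softmax temperature of the matched classifier

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise InvalidInputError(f"separation must be >= 0, got {self.separation}")
        if self.spread <= 0:
            raise InvalidInputError(f"spread must be > 0, got {self.spread}")
        if self.temperature <= 0:
            raise InvalidInputError(f"temperature must be > 0, got {self.temperature}")


def _default_specs() -> tuple[ModelSpec, ...]:
    # one strong, one middling, one weak feature extractor
    return (
        ModelSpec("model_a", separation=6.0, spread=1.0),
        ModelSpec("model_b", separation=3.0, spread=1.0),
        ModelSpec("model_c", separation=1.0, spread=1.0),
    )


@dataclass
class SynthConfig:
    """Study conditions for one synthetic ensemble.

    Defaults mirror a four-disease crop dataset of 2000 images split 3:2
    into training and test (300 / 200 images per class) with three member
    models of clearly ranked feature-extraction quality.
    """

    k: int = 4
    per_class_train: int = 300
    per_class_test: int = 200
    d: int = 16
    model_specs: tuple[ModelSpec, ...] = field(default_factory=_default_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InvalidInputError(f"need k >= 2 classes, got {self.k}")
        if self.d < 1:
            raise InvalidInputError(f"need d >= 1 feature dimensions, got {self.d}")
        if self.per_class_train < 1 or self.per_class_test < 1:
            raise InvalidInputError("per-class sample counts must be positive")
        if len(self.model_specs) < 1:
            raise InvalidInputError("need at least one model spec")
        ids = [m.model_id for m in self.model_specs]
        if len(set(ids)) != len(ids):
            raise InvalidInputError(f"duplicate model ids in {ids}")

    @property
    def class_ids(self) -> tuple[str, ...]:
        return tuple(f"class_{chr(ord('a') + p)}" for p in range(self.k))


def _class_means(k: int, d: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """Class means at distance ``separation`` from the origin.

    Directions are random orthonormal vectors when k <= d (all pairwise
    mean distances equal separation * sqrt(2)); for k > d orthogonality is
    impossible, so independent random unit directions are used instead.
    """
    raw = rng.standard_normal((d, k))
    if k <= d:
        q, _ = np.linalg.qr(raw)
        dirs = q[:, :k].T
    else:
        dirs = raw.T / np.linalg.norm(raw.T, axis=1, keepdims=True)
    return separation * dirs


def _sample_classes(
    means: np.ndarray,
    per_class: int,
    spread: float,
    class_ids: tuple[str, ...],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    k, d = means.shape
    vectors = np.empty((k * per_class, d))
    labels = np.empty(k * per_class, dtype=object)
    for p in range(k):
        block = slice(p * per_class, (p + 1) * per_class)
        vectors[block] = means[p] + spread * rng.standard_normal((per_class, d))
        labels[block] = class_ids[p]
    return vectors, labels


def generate_feature_space(
    k: int,
    per_class: int,
    d: int,
    separation: float,
    spread: float,
    seed: int | np.random.Generator,
    model_id: str = "",
    class_ids: tuple[str, ...] | None = None,
) -> FeatureVectorSet:
    """One model's feature space: k Gaussian clusters of ``per_class`` samples.

    ``spread`` may be 0 here to produce perfectly collapsed clusters (the
    degenerate geometry the separability statistics refuse to score).
    """
    if k < 2:
        raise InvalidInputError(f"need k >= 2 classes, got {k}")
    if d < 1:
        raise InvalidInputError(f"need d >= 1, got {d}")
    if spread < 0:
        raise InvalidInputError(f"spread must be >= 0, got {spread}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if class_ids is None:
        class_ids = tuple(f"class_{chr(ord('a') + p)}" for p in range(k))
    means = _class_means(k, d, separation, rng)
    vectors, labels = _sample_classes(means, per_class, spread, class_ids, rng)
    return FeatureVectorSet(vectors, labels, class_ids=class_ids, model_id=model_id)


def simulate_softmax(
    features: FeatureVectorSet,
    centroids: CentroidSet,
    temperature: float = 1.0,
    model_id: str | None = None,
) -> SoftmaxTable:
    """Centroid-distance softmax over a test split.

    Row for sample x: ``p_j ∝ exp(-d(x, cen_j) / T)``, normalised to 1.
    Computed in log space (shifted by the row minimum) for stability at
    small temperatures.
    """
    if temperature <= 0:
        raise InvalidInputError(f"temperature must be > 0, got {temperature}")
    if centroids.d != features.d:
        raise InvalidInputError(
            f"centroid dimension {centroids.d} does not match feature dimension {features.d}"
        )
    diffs = features.vectors[:, None, :] - centroids.centroids[None, :, :]
    dists = np.linalg.norm(diffs, axis=2)
    logits = -(dists - dists.min(axis=1, keepdims=True)) / temperature
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    return SoftmaxTable(
        probs,
        sample_ids=features.sample_ids,
        class_ids=centroids.class_ids,
        model_id=model_id if model_id is not None else features.model_id,
    )


@dataclass
class EnsembleData:
    """Everything one synthetic run produces, keyed by model id."""

    train_features: dict[str, FeatureVectorSet]
    softmax_tables: dict[str, SoftmaxTable]
    truth_sample_ids: tuple[str, ...]
    truth_labels: tuple[str, ...]
    config: SynthConfig


def generate_ensemble(config: SynthConfig, out_dir: str | Path | None = None) -> EnsembleData:
    """Simulate a full multi-model ensemble run.

    For every model spec: draw class means, a training feature space and a
    test feature space from them, then the centroid-distance softmax of
    the test split against the training centroids.  Truth labels are
    identical across models.  Identical config + seed reproduces identical
    data (and, with ``out_dir``, byte-identical files).
    """
    class_ids = config.class_ids
    n_test = config.k * config.per_class_test
    width = max(4, len(str(n_test)))
    test_sample_ids = tuple(f"t{i + 1:0{width}d}" for i in range(n_test))
    truth_labels = tuple(
        class_ids[p] for p in range(config.k) for _ in range(config.per_class_test)
    )

    seeds = np.random.SeedSequence(config.seed).spawn(len(config.model_specs))
    train_features: dict[str, FeatureVectorSet] = {}
    softmax_tables: dict[str, SoftmaxTable] = {}
    for spec, ss in zip(config.model_specs, seeds):
        rng = np.random.default_rng(ss)
        means = _class_means(config.k, config.d, spec.separation, rng)
        train_vec, train_lab = _sample_classes(
            means, config.per_class_train, spec.spread, class_ids, rng
        )
        test_vec, test_lab = _sample_classes(
            means, config.per_class_test, spec.spread, class_ids, rng
        )
        fvs = FeatureVectorSet(
            train_vec, train_lab, class_ids=class_ids, model_id=spec.model_id
        )
        test_fvs = FeatureVectorSet(
            test_vec,
            test_lab,
            class_ids=class_ids,
            model_id=spec.model_id,
            sample_ids=test_sample_ids,
        )
        table = simulate_softmax(
            test_fvs, compute_centroids(fvs), temperature=spec.temperature
        )
        train_features[spec.model_id] = fvs
        softmax_tables[spec.model_id] = table

    data = EnsembleData(train_features, softmax_tables, test_sample_ids, truth_labels, config)
    if out_dir is not None:
        from . import io as _io

        _io.write_ensemble_fixture(data, out_dir)
    return data
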