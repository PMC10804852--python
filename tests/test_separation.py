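"""Separability geometry: centroids, icD, bcD, FEP, ensemble weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ortho_group

from elcdr import (
    CentroidSet,
    DegenerateGeometryError,
    FeatureVectorSet,
    InvalidInputError,
    between_categories_distance,
    compute_centroids,
    ensemble_weights,
    euclidean_distance,
    feature_extraction_performance,
    in_category_distance,
)
from conftest import random_feature_set


def naive_icd(fvs):
    """Double-loop oracle: mean distance of each vector to its class centroid."""
    cents = {}
    for cid in fvs.class_ids:
        rows = [v for v, lab in zip(fvs.vectors, fvs.labels) if lab == cid]
        cents[cid] = [sum(col) / len(rows) for col in zip(*rows)]
    total = 0.0
    for v, lab in zip(fvs.vectors, fvs.labels):
        total += sum((a - b) ** 2 for a, b in zip(cents[lab], v)) ** 0.5
    return total / len(fvs.vectors)


def naive_bcd(cents):
    """Pair-enumeration oracle: mean distance over all unordered centroid pairs."""
    k = cents.k
    acc, pairs = 0.0, 0
    for p in range(k):
        for q in range(p + 1, k):
            acc += sum((a - b) ** 2 for a, b in zip(cents.centroids[p], cents.centroids[q])) ** 0.5
            pairs += 1
    return acc / pairs


class TestEuclideanDistance:
    def test_known_values(self):
        assert euclidean_distance((0, 0), (3, 4)) == pytest.approx(5.0, abs=1e-15)
        assert euclidean_distance((1, 1), (1, 1)) == 0.0

    def test_matches_loop_oracle_and_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        expected = sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
        assert euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_dimension_mismatch_names_both(self):
        with pytest.raises(InvalidInputError, match=r"\(2,\).*\(3,\)"):
            euclidean_distance((1, 2), (1, 2, 3))


class TestCentroids:
    def test_singleton_and_midpoint(self):
        fvs = FeatureVectorSet(
            np.array([[2.0, 7.0], [0.0, 0.0], [2.0, 2.0]]),
            np.array(["a", "b", "b"], dtype=object),
        )
        cents = compute_centroids(fvs)
        assert cents.centroids[0] == pytest.approx([2, 7])
        assert cents.centroids[1] == pytest.approx([1, 1])

    def test_matches_brute_force_means(self, rng):
        fvs = random_feature_set(rng, t=15, d=4, k=3)
        cents = compute_centroids(fvs)
        for p, cid in enumerate(fvs.class_ids):
            rows = fvs.vectors[fvs.labels == cid]
            acc = np.zeros(fvs.d)
            for r in rows:
                acc += r
            assert cents.centroids[p] == pytest.approx(acc / len(rows), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(InvalidInputError, match="'ghost'"):
            FeatureVectorSet(
                np.ones((2, 2)),
                np.array(["a", "b"], dtype=object),
                class_ids=("a", "b", "ghost"),
            )


class TestDistances:
    def test_icd_degenerate_and_symmetric_pairs(self):
        fvs = FeatureVectorSet(
            np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 3.0], [0.0, 5.0]]),
            np.array(["A", "A", "B", "B"], dtype=object),
        )
        assert in_category_distance(fvs) == pytest.approx(1.0, abs=1e-15)
        collapsed = FeatureVectorSet(
            np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]]),
            np.array(["A", "A", "B"], dtype=object),
        )
        assert in_category_distance(collapsed) == 0.0

    def test_bcd_single_pair_and_equilateral(self):
        assert between_categories_distance(
            CentroidSet(np.array([[0.0, 0.0], [3.0, 4.0]]), ("a", "b"))
        ) == pytest.approx(5.0, abs=1e-15)
        tri = np.array([[0, 0], [2, 0], [1, np.sqrt(3)]], dtype=float)
        assert between_categories_distance(
            CentroidSet(tri, ("a", "b", "c"))
        ) == pytest.approx(2.0, abs=1e-12)

    def test_bcd_requires_two_classes(self):
        with pytest.raises(InvalidInputError, match="undefined"):
            between_categories_distance(CentroidSet(np.ones((1, 3)), ("a",)))

    def test_oracle_equivalence_random_sets(self, rng):
        for _ in range(20):
            fvs = random_feature_set(rng)
            cents = compute_centroids(fvs)
            assert in_category_distance(fvs, cents) == pytest.approx(
                naive_icd(fvs), abs=1e-12
            )
            assert between_categories_distance(cents) == pytest.approx(
                naive_bcd(cents), abs=1e-12
            )


class TestFEP:
    @pytest.mark.parametrize(
        "icd, bcd, fep",
        [(2.051201, 1.807103, 0.880997), (4.639691, 20.89895, 4.504383)],
    )
    def test_ratio_matches_published_rows(self, icd, bcd, fep):
        # published rows give only (icD, bcD); the ratio must reproduce FEP
        assert bcd / icd == pytest.approx(fep, rel=5e-6)

    def test_bcd_equals_icd_gives_unit_fep(self, rng):
        fvs = random_feature_set(rng, t=30, d=3, k=3)
        stats = feature_extraction_performance(fvs)
        assert stats.fep == pytest.approx(stats.bcd / stats.icd, abs=1e-15)
        # rescale within-class residuals so icD == bcD exactly
        cents = compute_centroids(fvs)
        cent_of = {c: cents.centroids[i] for i, c in enumerate(fvs.class_ids)}
        resid = fvs.vectors - np.array([cent_of[l] for l in fvs.labels])
        scaled = np.array([cent_of[l] for l in fvs.labels]) + resid * (
            stats.bcd / stats.icd
        )
        unit = FeatureVectorSet(scaled, fvs.labels, class_ids=fvs.class_ids)
        assert feature_extraction_performance(unit).fep == pytest.approx(1.0, rel=1e-9)

    def test_collapsed_clusters_raise_unless_clamped(self):
        fvs = FeatureVectorSet(
            np.array([[0.0, 0.0], [0.0, 0.0], [4.0, 0.0]]),
            np.array(["a", "a", "b"], dtype=object),
        )
        with pytest.raises(DegenerateGeometryError):
            feature_extraction_performance(fvs)
        clamped = feature_extraction_performance(fvs, icd_epsilon=1e-6)
        assert clamped.icd == 1e-6
        assert clamped.fep == pytest.approx(4.0 / 1e-6)

    def test_rigid_transform_invariance(self, rng):
        fvs = random_feature_set(rng, t=40, d=5, k=4)
        base = feature_extraction_performance(fvs)
        rot = ortho_group.rvs(5, random_state=7)
        shift = rng.normal(size=5) * 10
        moved = FeatureVectorSet(
            fvs.vectors @ rot.T + shift, fvs.labels, class_ids=fvs.class_ids
        )
        got = feature_extraction_performance(moved)
        assert got.icd == pytest.approx(base.icd, rel=1e-9)
        assert got.bcd == pytest.approx(base.bcd, rel=1e-9)
        assert got.fep == pytest.approx(base.fep, rel=1e-9)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_covariance(self, c):
        rng = np.random.default_rng(5)
        fvs = random_feature_set(rng, t=25, d=4, k=3)
        base = feature_extraction_performance(fvs)
        scaled = FeatureVectorSet(fvs.vectors * c, fvs.labels, class_ids=fvs.class_ids)
        got = feature_extraction_performance(scaled)
        assert got.icd == pytest.approx(c * base.icd, rel=1e-9)
        assert got.bcd == pytest.approx(c * base.bcd, rel=1e-9)
        assert got.fep == pytest.approx(base.fep, rel=1e-9)

    def test_monotone_separability(self):
        # push two class means apart at fixed spread: FEP strictly increases
        rng = np.random.default_rng(11)
        resid = rng.normal(size=(20, 3))
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        feps = []
        for gap in (1.0, 2.0, 4.0, 8.0):
            vectors = resid.copy()
            vectors[10:, 0] += gap
            feps.append(
                feature_extraction_performance(FeatureVectorSet(vectors, labels)).fep
            )
        assert all(a < b for a, b in zip(feps, feps[1:]))


class TestEnsembleWeights:
    def test_matches_published_weight_columns(self):
        w = ensemble_weights([0.880997, 2.801886, 2.447378])
        assert w.weights * 100 == pytest.approx([14.371, 45.706, 39.923], abs=5e-4)
        w = ensemble_weights([0.431525, 1.951684, 1.905859])
        assert w.weights[0] == pytest.approx(0.10061, abs=5e-6)

    def test_symmetry_and_normalization(self, rng):
        w = ensemble_weights([2.0, 2.0, 2.0])
        assert w.weights == pytest.approx([1 / 3] * 3)
        feps = rng.random(6) + 0.1
        w = ensemble_weights(feps)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert list(np.argsort(w.weights)) == list(np.argsort(feps))

    @pytest.mark.parametrize("bad", [[], [1.0, 0.0], [1.0, -2.0], [1.0, float("nan")]])
    def test_invalid_fep_lists_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            ensemble_weights(bad)

    def test_single_model_gets_weight_one(self):
        w = ensemble_weights([3.7], ["only"])
        assert w.as_dict() == {"only": 1.0}
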