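import numpy as np
import pytest

from elcdr import FeatureVectorSet, SoftmaxTable


def random_feature_set(rng, t=None, d=None, k=None, model_id="m"):
    """Random labeled feature set with every class guaranteed nonempty."""
    k = k if k is not None else int(rng.integers(2, 6))
    d = d if d is not None else int(rng.integers(1, 9))
    t = t if t is not None else int(rng.integers(k, 51))
    class_ids = tuple(f"c{j}" for j in range(k))
    labels = np.array(
        list(class_ids) + [class_ids[i] for i in rng.integers(0, k, size=t - k)],
        dtype=object,
    )
    vectors = rng.normal(size=(t, d))
    return FeatureVectorSet(vectors, labels, class_ids=class_ids, model_id=model_id)


def random_softmax_table(rng, s, k, sample_ids=None, class_ids=None, model_id="m"):
    """Random valid softmax table via normalized Dirichlet-style rows."""
    raw = rng.random((s, k)) + 1e-3
    probs = raw / raw.sum(axis=1, keepdims=True)
    if sample_ids is None:
        sample_ids = tuple(f"s{i}" for i in range(s))
    if class_ids is None:
        class_ids = tuple(f"c{j}" for j in range(k))
    return SoftmaxTable(probs, sample_ids, class_ids, model_id=model_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
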