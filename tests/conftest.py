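import numpy as np
import pytest

from metimpute.table import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, class_labels=None, is_qc=None, feature_ids=None):
    """Helper building a FeatureTable around a plain matrix."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if class_labels is None:
        class_labels = np.array(["c1"] * n, dtype=object)
    return FeatureTable(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=feature_ids or [f"f{j}" for j in range(p)],
        class_labels=np.asarray(class_labels, dtype=object),
        is_qc=is_qc,
    )


@pytest.fixture
def tiny_table():
    return make_table(
        [[1.0, 2.0, 3.0], [4.0, np.nan, 6.0], [7.0, 8.0, 9.0]],
        class_labels=["a", "a", "b"],
    )


@pytest.fixture
def separable_classes(rng):
    """Three spherical classes with centroids 10x the within-class sd apart."""
    # non-collinear centroids: collinear class means mask the middle class
    # under linear dummy-response classification
    centers = np.zeros((3, 8))
    centers[0, 0] = 10.0
    centers[1, 1] = 10.0
    centers[2, 2] = 10.0
    x = np.vstack([c + rng.normal(scale=1.0, size=(20, 8)) for c in centers])
    x = x - x.min() + 1.0  # keep intensities positive
    labels = np.repeat(["n1", "n2", "n3"], 20)
    return make_table(x, class_labels=labels)
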