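import numpy as np
import pytest

from bhcmda import AssociationData, DiseaseDAG, SimilarityMatrix


@pytest.fixture
def toy_assoc():
    """The 3-miRNA x 2-disease worked example network."""
    return AssociationData(
        ["m1", "m2", "m3"], ["d1", "d2"], np.array([[1, 0], [1, 1], [0, 1]])
    )


@pytest.fixture
def shared_root_dags():
    """Two diseases hanging off one shared root term."""
    return {
        "d1": DiseaseDAG("d1", {"d1", "r"}, {("r", "d1")}),
        "d2": DiseaseDAG("d2", {"d2", "r"}, {("r", "d2")}),
    }


def make_sim(labels, values, role="SM", coverage=None):
    return SimilarityMatrix(list(labels), np.asarray(values, float), role, coverage)


def random_similarity(rng, labels, role="SM"):
    """Random symmetric matrix in [0, 1] with unit diagonal."""
    k = len(labels)
    raw = rng.random((k, k))
    vals = (raw + raw.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(list(labels), vals, role)


def random_assoc(rng, n, q, density=0.4):
    """Random binary association matrix guaranteed nonempty."""
    A = (rng.random((n, q)) < density).astype(np.int8)
    if A.sum() == 0:
        A[rng.integers(n), rng.integers(q)] = 1
    return AssociationData(
        [f"m{i}" for i in range(n)], [f"d{j}" for j in range(q)], A
    )
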