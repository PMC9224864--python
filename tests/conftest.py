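import numpy as np
import pytest

from mdmf.io import AssociationMatrix, DiseaseDAG, WeightMatrix
from mdmf.similarity import SimilarityMatrix


@pytest.fixture
def toy_assoc() -> AssociationMatrix:
    """3 miRNAs x 3 diseases with 3 known pairs, used by LOOCV hand enumerations."""
    y = np.array(
        [
            [1, 0, 0],
            [0, 1, 0],
            [0, 0, 1],
        ],
        dtype=float,
    )
    return AssociationMatrix(["m1", "m2", "m3"], ["d1", "d2", "d3"], y)


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    """A -> B -> D with delta = 0.5."""
    return DiseaseDAG(
        nodes=frozenset({"A", "B", "D"}),
        parent_edges=frozenset({("A", "B"), ("B", "D")}),
        delta=0.5,
    )


@pytest.fixture
def diamond_dag() -> DiseaseDAG:
    """A -> B -> D and A -> C -> D with delta = 0.5."""
    return DiseaseDAG(
        nodes=frozenset({"A", "B", "C", "D"}),
        parent_edges=frozenset({("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")}),
        delta=0.5,
    )


def random_instance(seed: int, p: int = 4, q: int = 3, k: int = 3):
    """A small random (assoc, weights, sim, M, D) problem for gradient checks."""
    rng = np.random.default_rng(seed)
    y = (rng.random((p, q)) < 0.4).astype(float)
    w = rng.random((p, q))
    w[y == 1] = 1.0
    s = rng.random((q, q))
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 1.0)
    assoc = AssociationMatrix(
        [f"m{i}" for i in range(p)], [f"d{j}" for j in range(q)], y
    )
    weights = WeightMatrix(w=w, unobserved=np.minimum(w, rng.random((p, q))))
    sim = SimilarityMatrix(list(assoc.disease_ids), np.clip(s, 0, 1), "integrated")
    M = rng.standard_normal((k, p))
    D = rng.standard_normal((k, q)) + 0.5  # shift away from zero columns
    return assoc, weights, sim, M, D
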