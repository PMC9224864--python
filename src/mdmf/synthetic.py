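"""Seeded synthetic fixtures with the statistical structure the model assumes.

The planted-dataset generator draws nonnegative low-rank factors, marks the
top-scoring entries of their (noisy) product as known associations, exposes
the exact cosine matrix of the planted disease factors as the integrated
similarity, and derives confidence weights from a synthetic expression
table correlated with the true scores.  Everything is reproducible from a
single integer seed, which makes recovery experiments and ablations exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    AssociationMatrix,
    DiseaseDAG,
    ExpressionTable,
    WeightMatrix,
    build_weight_matrix,
)
from .similarity import SimilarityMatrix

__all__ = [
    "SyntheticDataset",
    "generate_planted",
    "generate_random_dag",
    "generate_expression",
]


@dataclass
class SyntheticDataset:
    assoc: AssociationMatrix
    weights: WeightMatrix
    sim: SimilarityMatrix
    dag: DiseaseDAG
    true_M: np.ndarray
    true_D: np.ndarray
    seed: int
    params: dict


def _mirna_names(p: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(p)]


def _disease_names(q: int) -> list[str]:
    return [f"D{j:04d}" for j in range(q)]


def generate_planted(
    p: int = 100,
    q: int = 40,
    k: int = 5,
    density: float = 0.05,
    noise: float = 0.1,
    seed: int = 0,
    expression_signal: float = 0.7,
) -> SyntheticDataset:
    """Plant a rank-k association structure.

    True factors are i.i.d. uniform nonnegative; ``y_ij = 1`` for the top
    ``ceil(density * p * q)`` entries of ``true_M^T true_D + noise * eps``
    (Gaussian eps), so the planted count is exact.  The similarity matrix
    is the pairwise cosine of the true disease factors, and the confidence
    weights come from a synthetic expression draw whose correlation with
    the true scores is set by ``expression_signal``.
    """
    if not (0 < density < 1):
        raise ValueError("density must lie in (0, 1)")
    n_ones = int(np.ceil(density * p * q))
    if n_ones < 2:
        raise ValueError("density * p * q must be at least 2")
    rng = np.random.default_rng(seed)
    true_M = rng.uniform(0.0, 1.0, size=(k, p))
    true_D = rng.uniform(0.0, 1.0, size=(k, q))
    scores = true_M.T @ true_D
    noisy = scores + noise * rng.standard_normal(scores.shape)
    flat = np.argsort(-noisy, axis=None, kind="stable")[:n_ones]
    y = np.zeros((p, q))
    y[np.unravel_index(flat, y.shape)] = 1.0

    mirna_ids = _mirna_names(p)
    disease_ids = _disease_names(q)
    assoc = AssociationMatrix(mirna_ids, disease_ids, y)

    norms = np.linalg.norm(true_D, axis=0)
    cos = (true_D / norms).T @ (true_D / norms)
    sim = SimilarityMatrix(disease_ids, np.clip(cos, 0.0, 1.0), kind="integrated")

    expr = generate_expression(
        p,
        q,
        signal=expression_signal,
        seed=int(rng.integers(2**31)),
        truth=scores,
        mirna_ids=mirna_ids,
        disease_ids=disease_ids,
    )
    weights = build_weight_matrix(assoc, expr)
    dag = generate_random_dag(q, layers=3, branching=2, seed=int(rng.integers(2**31)))
    return SyntheticDataset(
        assoc=assoc,
        weights=weights,
        sim=sim,
        dag=dag,
        true_M=true_M,
        true_D=true_D,
        seed=seed,
        params={
            "p": p,
            "q": q,
            "k": k,
            "density": density,
            "noise": noise,
            "expression_signal": expression_signal,
        },
    )


def generate_random_dag(
    n: int,
    layers: int = 3,
    branching: int = 2,
    seed: int = 0,
    delta: float = 0.5,
) -> DiseaseDAG:
    """Layered random DAG: each non-root node gets 1..branching parents above it.

    Acyclic by construction (edges only point from earlier to later layers).
    """
    if n < 1 or layers < 1:
        raise ValueError("need n >= 1 and layers >= 1")
    if layers > n:
        raise ValueError(f"cannot fill {layers} layers with {n} nodes")
    rng = np.random.default_rng(seed)
    names = _disease_names(n)
    # distribute nodes over layers, every layer nonempty
    base, extra = divmod(n, layers)
    sizes = [base + (1 if i < extra else 0) for i in range(layers)]
    layer_of: list[list[str]] = []
    start = 0
    for s in sizes:
        layer_of.append(names[start : start + s])
        start += s
    edges: set[tuple[str, str]] = set()
    for li in range(1, layers):
        above = layer_of[li - 1]
        for child in layer_of[li]:
            n_par = int(rng.integers(1, branching + 1))
            parents = rng.choice(above, size=min(n_par, len(above)), replace=False)
            for par in parents:
                edges.add((str(par), child))
    return DiseaseDAG(nodes=frozenset(names), parent_edges=frozenset(edges), delta=delta)


def generate_expression(
    p: int,
    q: int,
    signal: float,
    seed: int = 0,
    truth: np.ndarray | None = None,
    mirna_ids: "list[str] | None" = None,
    disease_ids: "list[str] | None" = None,
) -> ExpressionTable:
    """Per-(miRNA, condition) expression: signal * scaled truth + (1-signal) * noise.

    ``signal = 0`` gives truth-independent uniform noise; ``signal = 1``
    gives a monotone transform of the truth.  Values are min-max normalized
    to [0, 1].
    """
    if not (0 <= signal <= 1):
        raise ValueError("signal must lie in [0, 1]")
    if signal > 0 and truth is None:
        raise ValueError("signal > 0 requires a truth score matrix")
    rng = np.random.default_rng(seed)
    mirna_ids = mirna_ids if mirna_ids is not None else _mirna_names(p)
    disease_ids = disease_ids if disease_ids is not None else _disease_names(q)
    noise = rng.uniform(0.0, 1.0, size=(p, q))
    if truth is not None:
        t = np.asarray(truth, dtype=float)
        lo, hi = t.min(), t.max()
        scaled = (t - lo) / (hi - lo) if hi > lo else np.zeros_like(t)
        values = signal * scaled + (1 - signal) * noise
    else:
        values = noise
    lo, hi = values.min(), values.max()
    values = (values - lo) / (hi - lo) if hi > lo else values
    mirnas, conds, vals = [], [], []
    for i, m in enumerate(mirna_ids):
        for j, d in enumerate(disease_ids):
            mirnas.append(m)
            conds.append(d)
            vals.append(values[i, j])
    return ExpressionTable.from_arrays(mirnas, np.asarray(vals), conditions=conds)
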