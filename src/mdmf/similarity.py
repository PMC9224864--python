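"""Disease-disease similarity: DAG semantic (Wang), GIP kernel, and their integration.

Semantic similarity follows the Wang construction: within the sub-DAG
``DAG(D) = (D, T(D), E(D))`` of a disease ``D`` — its ancestor closure —
every ancestor ``d`` contributes

    DD_D(D) = 1
    DD_D(d) = max{ delta * DD_D(d') : d' a child of d inside T(D) }   (d != D)

with decay factor ``delta`` in (0, 1].  ``DV(D) = sum_t DD_D(t)`` and

    SS(i, j) = sum_{t in T(i) ∩ T(j)} (DD_i(t) + DD_j(t)) / (DV(i) + DV(j)),

a value in [0, 1] with SS(d, d) = 1.

The Gaussian interaction profile (GIP) kernel compares binary association
profiles IP(d) (columns of the association matrix):

    GS(i, j) = exp(-r * ||IP(d_i) - IP(d_j)||^2),
    r = r' / mean_i ||IP(d_i)||^2.

Integration takes SS wherever it is defined (both diseases covered by the
DAG by default) and falls back to GS elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import AssociationMatrix, DiseaseDAG

__all__ = [
    "SemanticContribution",
    "SimilarityMatrix",
    "GipBandwidth",
    "semantic_contributions",
    "semantic_similarity",
    "semantic_similarity_matrix",
    "gip_bandwidth",
    "gip_similarity",
    "integrate_similarity",
    "integrated_similarity",
]


@dataclass
class SemanticContribution:
    """Per-ancestor semantic contributions DD_D(t) and their sum DV(D)."""

    disease: str
    contributions: dict[str, float]
    semantic_value: float


@dataclass
class SimilarityMatrix:
    """Symmetric disease similarity matrix with entries in [0, 1]."""

    disease_ids: list[str]
    values: np.ndarray
    kind: str  # semantic | gip | integrated

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        q = len(self.disease_ids)
        if self.values.shape != (q, q):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({q}, {q})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        # clamp tiny float excursions, then validate
        self.values = np.clip(0.5 * (self.values + self.values.T), 0.0, 1.0)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.disease_ids) + "\n")
            for d, row in zip(self.disease_ids, self.values):
                fh.write(d + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def read(cls, path, kind: str = "integrated") -> "SimilarityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in fields[1:]])
        return cls(disease_ids=header, values=np.array(rows), kind=kind)


@dataclass
class GipBandwidth:
    """GIP kernel bandwidth r = r' / mean squared profile norm over n_d diseases."""

    r_prime: float
    r: float
    n_d: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r) and self.r > 0):
            raise ValueError(f"bandwidth must be finite and positive, got {self.r}")


def semantic_contributions(dag: DiseaseDAG, disease: str) -> SemanticContribution:
    """Compute DD_D(t) for every ancestor t of ``disease`` by upward recursion.

    The recursion is restricted to T(D): a node's contribution flows only
    through children that themselves lie on a path toward D.
    """
    if disease not in dag:
        raise KeyError(f"disease not in DAG: {disease!r}")
    ancestry = dag.ancestors(disease)
    sub = dag.graph.subgraph(ancestry)
    contributions: dict[str, float] = {}
    # reverse topological order: disease first, then progressively higher ancestors
    for node in reversed(list(nx.topological_sort(sub))):
        if node == disease:
            contributions[node] = 1.0
        else:
            contributions[node] = dag.delta * max(
                contributions[c] for c in sub.successors(node)
            )
    return SemanticContribution(
        disease=disease,
        contributions=contributions,
        semantic_value=float(sum(contributions.values())),
    )


def semantic_similarity(dag: DiseaseDAG, d_i: str, d_j: str) -> float:
    """Wang semantic similarity between two diseases of the DAG."""
    ci = semantic_contributions(dag, d_i)
    cj = semantic_contributions(dag, d_j)
    shared = set(ci.contributions) & set(cj.contributions)
    num = sum(ci.contributions[t] + cj.contributions[t] for t in shared)
    return float(np.clip(num / (ci.semantic_value + cj.semantic_value), 0.0, 1.0))


def semantic_similarity_matrix(
    dag: DiseaseDAG,
    disease_ids: "list[str]",
) -> tuple[SimilarityMatrix, np.ndarray]:
    """SS over ``disease_ids`` plus the coverage mask of pairs with both ids in the DAG.

    Entries outside the mask are 0 placeholders; they are never read by
    :func:`integrate_similarity`.
    """
    q = len(disease_ids)
    covered = np.array([d in dag for d in disease_ids], dtype=bool)
    contribs = {
        d: semantic_contributions(dag, d) for d, c in zip(disease_ids, covered) if c
    }
    values = np.zeros((q, q))
    for j in range(q):
        if not covered[j]:
            continue
        cj = contribs[disease_ids[j]]
        values[j, j] = 1.0
        for k in range(j + 1, q):
            if not covered[k]:
                continue
            ck = contribs[disease_ids[k]]
            shared = set(cj.contributions) & set(ck.contributions)
            num = sum(cj.contributions[t] + ck.contributions[t] for t in shared)
            values[j, k] = values[k, j] = num / (cj.semantic_value + ck.semantic_value)
    mask = np.outer(covered, covered)
    return SimilarityMatrix(list(disease_ids), values, kind="semantic"), mask


def gip_bandwidth(assoc: AssociationMatrix, r_prime: float = 1.0) -> GipBandwidth:
    """Bandwidth r normalized by the mean squared interaction-profile norm."""
    if r_prime <= 0:
        raise ValueError("r_prime must be positive")
    profiles = assoc.y  # columns are IP(d)
    mean_sq = float(np.mean(np.sum(profiles**2, axis=0)))
    if mean_sq == 0:
        raise ValueError("zero mean profile norm: no disease has any association")
    return GipBandwidth(r_prime=r_prime, r=r_prime / mean_sq, n_d=profiles.shape[1])


def gip_similarity(assoc: AssociationMatrix, bandwidth: GipBandwidth) -> SimilarityMatrix:
    """Gaussian kernel on disease interaction profiles."""
    profiles = assoc.y.T  # one row per disease
    d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-bandwidth.r * d2)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(assoc.disease_ids), values, kind="gip")


def integrate_similarity(
    ss: SimilarityMatrix,
    gs: SimilarityMatrix,
    semantic_coverage: np.ndarray,
) -> SimilarityMatrix:
    """Semantic similarity where defined, GIP similarity otherwise."""
    if ss.disease_ids != gs.disease_ids:
        raise ValueError("semantic and GIP matrices are not index-aligned")
    mask = np.asarray(semantic_coverage, dtype=bool)
    if mask.shape != ss.values.shape:
        raise ValueError("coverage mask shape mismatch")
    values = np.where(mask, ss.values, gs.values)
    return SimilarityMatrix(list(ss.disease_ids), values, kind="integrated")


def integrated_similarity(
    assoc: AssociationMatrix,
    dag: DiseaseDAG,
    r_prime: float = 1.0,
    coverage: str = "membership",
) -> SimilarityMatrix:
    """Full pipeline: SS over the DAG, GS from profiles, then the fallback merge.

    ``coverage`` selects when a pair "has" semantic similarity:
    ``membership`` (default) — both diseases appear in the DAG;
    ``positive`` — additionally SS > 0 (pairs with no shared ancestor fall
    back to GIP).
    """
    if coverage not in ("membership", "positive"):
        raise ValueError(f"unknown coverage rule: {coverage!r}")
    ss, mask = semantic_similarity_matrix(dag, assoc.disease_ids)
    if coverage == "positive":
        # covered diagonals keep SS (=1); uncovered ones already fall to GIP
        mask = mask & (ss.values > 0)
    gs = gip_similarity(assoc, gip_bandwidth(assoc, r_prime))
    return integrate_similarity(ss, gs, mask)
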