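"""Weighted matrix factorization with a disease-similarity cosine constraint.

The model learns a latent matrix M (k x p, one column per miRNA) and
D (k x q, one column per disease) minimizing

    L = 1/2 [ sum_ij w_ij (r_ij - d_j^T m_i)^2
              + alpha * sum_{j<k} (S_jk - cos(d_j, d_k))^2
              + lambda1 ||M||_F^2 + lambda2 ||D||_F^2 ]

where r_ij is the binary association, w_ij a per-entry confidence weight
(1 on observed associations, expression-derived on unobserved ones), S the
integrated disease similarity, and cos the cosine between disease latent
vectors.  The constraint pulls the geometry of the disease latent space
toward the integrated similarity matrix; alpha trades it off against the
data term.  Training is deterministic full-batch gradient descent from a
seeded uniform-positive initialization, and predicted association scores
are the inner products m_i . d_j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AssociationMatrix, WeightMatrix
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "LatentFactors",
    "ScoreMatrix",
    "init_factors",
    "objective",
    "grad_mirna",
    "grad_disease",
    "full_gradients",
    "train",
    "predict_scores",
]

_NORM_GUARD = 1e-12


@dataclass
class TrainConfig:
    """Hyperparameters of the factorization.

    alpha is the similarity-constraint trade-off (0.7 is the value at which
    the constraint helps most before over-regularizing); lambda1/lambda2
    are Frobenius penalties on the two latent matrices; eta the step size
    of full-batch gradient descent; tol the relative objective-decrease
    stopping tolerance.
    """

    k: int = 40
    alpha: float = 0.7
    lambda1: float = 0.01
    lambda2: float = 0.01
    eta: float = 0.01
    max_epochs: int = 500
    tol: float = 1e-6
    seed: int = 0
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha < 0 or self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("alpha, lambda1, lambda2 must be nonnegative")
        if self.eta <= 0 or self.init_scale <= 0:
            raise ValueError("eta and init_scale must be positive")
        if self.max_epochs < 1 or self.tol < 0:
            raise ValueError("max_epochs must be >= 1 and tol >= 0")


@dataclass
class LatentFactors:
    """Latent matrices: column m_i of M for miRNA i, column d_j of D for disease j."""

    M: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.M.ndim != 2 or self.D.ndim != 2 or self.M.shape[0] != self.D.shape[0]:
            raise ValueError("M and D must be k x p and k x q with matching k")
        if not (np.isfinite(self.M).all() and np.isfinite(self.D).all()):
            raise ValueError("latent factors must be finite")

    @property
    def k(self) -> int:
        return self.M.shape[0]


@dataclass
class ScoreMatrix:
    """p x q association scores m_i . d_j, index-aligned with the association matrix."""

    mirna_ids: list[str]
    disease_ids: list[str]
    scores: np.ndarray

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.disease_ids) + "\n")
            for m, row in zip(self.mirna_ids, self.scores):
                fh.write(m + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def init_factors(p: int, q: int, cfg: TrainConfig) -> LatentFactors:
    """Seeded i.i.d. uniform initialization on (0, init_scale].

    Strictly positive entries guarantee nonzero disease columns, so every
    cosine in the constraint is defined from the first epoch.
    """
    rng = np.random.default_rng(cfg.seed)
    M = (1.0 - rng.random((cfg.k, p))) * cfg.init_scale
    D = (1.0 - rng.random((cfg.k, q))) * cfg.init_scale
    return LatentFactors(M=M, D=D)


def _cosine_matrix(D: np.ndarray, guard: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (C, U, norms): pairwise cosines of D's columns, normalized columns, norms."""
    norms = np.linalg.norm(D, axis=0)
    if np.any(norms < _NORM_GUARD):
        if not guard:
            raise ValueError("undefined cosine: a disease latent column is zero")
        logger.warning("disease latent column norm below guard; regularizing denominator")
        norms = norms + _NORM_GUARD
    U = D / norms
    return U.T @ U, U, norms


def objective(
    factors: LatentFactors,
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    sim: SimilarityMatrix,
    cfg: TrainConfig,
) -> float:
    """Value of the regularized weighted-least-squares objective."""
    M, D = factors.M, factors.D
    Y, W, S = assoc.y, weights.w, sim.values
    resid = M.T @ D - Y
    data = float(np.sum(W * resid**2))
    constraint = 0.0
    if cfg.alpha > 0:
        C, _, _ = _cosine_matrix(D)
        diff = S - C
        constraint = float(np.sum(np.triu(diff, k=1) ** 2))
    reg = cfg.lambda1 * float(np.sum(M**2)) + cfg.lambda2 * float(np.sum(D**2))
    return 0.5 * (data + cfg.alpha * constraint + reg)


def grad_mirna(
    factors: LatentFactors,
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    cfg: TrainConfig,
    i: int,
) -> np.ndarray:
    """Gradient of the objective in the latent vector of miRNA i."""
    M, D = factors.M, factors.D
    resid = weights.w[i] * (D.T @ M[:, i] - assoc.y[i])  # length q
    return D @ resid + cfg.lambda1 * M[:, i]


def grad_disease(
    factors: LatentFactors,
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    sim: SimilarityMatrix,
    cfg: TrainConfig,
    j: int,
) -> np.ndarray:
    """Gradient of the objective in the latent vector of disease j.

    The constraint part sums over all partners k != j: each unordered pair
    of the j<k sum contributes to both members' gradients.
    """
    M, D = factors.M, factors.D
    resid = weights.w[:, j] * (M.T @ D[:, j] - assoc.y[:, j])  # length p
    g = M @ resid + cfg.lambda2 * D[:, j]
    if cfg.alpha > 0:
        C, U, norms = _cosine_matrix(D)
        d_j, n_j = D[:, j], norms[j]
        for k in range(D.shape[1]):
            if k == j:
                continue
            # d cos(d_j, d_k) / d d_j = d_k/(|d_j||d_k|) - cos * d_j/|d_j|^2
            dcos = U[:, k] / n_j - C[j, k] * d_j / n_j**2
            g += cfg.alpha * (sim.values[j, k] - C[j, k]) * (-dcos)
    return g


def full_gradients(
    factors: LatentFactors,
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    sim: SimilarityMatrix,
    cfg: TrainConfig,
    guard: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gradients in all of M and D at once (used by training)."""
    M, D = factors.M, factors.D
    Y, W, S = assoc.y, weights.w, sim.values
    E = W * (M.T @ D - Y)  # p x q weighted residuals
    GM = D @ E.T + cfg.lambda1 * M
    GD = M @ E + cfg.lambda2 * D
    if cfg.alpha > 0:
        C, U, norms = _cosine_matrix(D, guard=guard)
        A = S - C
        np.fill_diagonal(A, 0.0)
        # column j of the constraint gradient:
        #   -sum_k A_jk [ u_k/n_j - C_jk u_j/n_j ]
        GD += cfg.alpha * (-(U @ A) + U * np.sum(A * C, axis=0)) / norms
    return GM, GD


@dataclass
class TrainingLog:
    """Objective value per epoch plus the stopping reason."""

    objective: list[float] = field(default_factory=list)
    stopped: str = "max_epochs"


def train(
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    sim: SimilarityMatrix,
    cfg: TrainConfig,
) -> tuple[LatentFactors, TrainingLog]:
    """Full-batch gradient descent from the seeded initialization.

    Both latent matrices step simultaneously against their gradients each
    epoch.  Stops at ``max_epochs`` or when the relative objective decrease
    falls below ``tol``; raises if the objective becomes non-finite.
    """
    p, q = assoc.shape
    if weights.w.shape != (p, q):
        raise ValueError("weight matrix shape mismatch")
    if sim.values.shape != (q, q):
        raise ValueError("similarity matrix shape mismatch")
    factors = init_factors(p, q, cfg)
    log = TrainingLog()
    prev = objective(factors, assoc, weights, sim, cfg)
    log.objective.append(prev)
    for _epoch in range(cfg.max_epochs):
        # overflow here only means divergence, which the finiteness check reports
        with np.errstate(over="ignore", invalid="ignore"):
            GM, GD = full_gradients(factors, assoc, weights, sim, cfg, guard=True)
            factors.M -= cfg.eta * GM
            factors.D -= cfg.eta * GD
            cur = objective_guarded(factors, assoc, weights, sim, cfg)
        if not np.isfinite(cur):
            raise FloatingPointError(
                "objective diverged (non-finite); try a smaller learning rate eta"
            )
        log.objective.append(cur)
        if prev > 0 and abs(prev - cur) / max(prev, _NORM_GUARD) < cfg.tol:
            log.stopped = "tol"
            break
        prev = cur
    return factors, log


def objective_guarded(
    factors: LatentFactors,
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    sim: SimilarityMatrix,
    cfg: TrainConfig,
) -> float:
    """Objective with the small-norm cosine guard instead of an error (training path)."""
    M, D = factors.M, factors.D
    resid = M.T @ D - assoc.y
    data = float(np.sum(weights.w * resid**2))
    constraint = 0.0
    if cfg.alpha > 0:
        C, _, _ = _cosine_matrix(D, guard=True)
        diff = sim.values - C
        constraint = float(np.sum(np.triu(diff, k=1) ** 2))
    reg = cfg.lambda1 * float(np.sum(M**2)) + cfg.lambda2 * float(np.sum(D**2))
    return 0.5 * (data + cfg.alpha * constraint + reg)


def predict_scores(factors: LatentFactors, assoc: AssociationMatrix) -> ScoreMatrix:
    """Association scores: the inner product of the two latent spaces."""
    scores = factors.M.T @ factors.D
    return ScoreMatrix(
        mirna_ids=list(assoc.mirna_ids),
        disease_ids=list(assoc.disease_ids),
        scores=scores,
    )
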