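"""LOOCV protocols, ranking metrics and candidate ranking.

Each known association is held out in turn: its entry is zeroed, its loss
weight reverts to the unobserved-entry weight, the model retrains from the
same seeded initialization, and the held-out pair is ranked among the
candidate pairs of the fold — every zero entry of the fold's training
matrix (global protocol) or only the zeros of the held-out disease's
column (local protocol).  Held-out scores (positives) and candidate scores
(negatives) pool across folds into one ranking universe from which AUC,
AUPR and threshold metrics are computed.

AUC uses the Mann-Whitney formulation with ties counted one half.  The
threshold for F1/ACC/MCC is not fixed a priori: all distinct scores are
swept and metrics are reported at the F1-maximizing threshold, which is
recorded in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .factorization import TrainConfig, predict_scores, train
from .factorization import ScoreMatrix
from .io import AssociationMatrix, WeightMatrix
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FoldResult",
    "MetricReport",
    "auc_from_ranks",
    "average_precision",
    "confusion_metrics",
    "best_f1_threshold",
    "global_loocv",
    "local_loocv",
    "rank_candidates",
]

Scorer = Callable[[AssociationMatrix, WeightMatrix], np.ndarray]


@dataclass
class FoldResult:
    """Outcome of one leave-one-out fold."""

    held_out_pair: tuple[str, str]
    rank: float  # midrank among candidates, 1-based
    candidate_count: int  # candidates excluding the held-out pair itself
    score: float


@dataclass
class MetricReport:
    auc: float
    aupr: float
    f1: float
    acc: float
    mcc: float
    threshold_used: float
    protocol: str


def auc_from_ranks(
    positive_scores: Sequence[float], negative_scores: Sequence[float]
) -> float:
    """P(random positive outscores random negative), ties counted 1/2."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    # rank-sum formulation; O((n+m) log(n+m))
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step-wise integration.

    AP = sum_k (R_k - R_{k-1}) * P_k over the descending-score sweep, i.e.
    the mean of precision at each positive's position (ties share the
    precision of their score block).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0 or y.sum() == 0:
        raise ValueError("need at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, s.size + 1)
    # collapse tied scores: all items of a tie block get the block-end precision
    block_end = np.ones(s.size, dtype=bool)
    block_end[:-1] = s[:-1] != s[1:]
    end_idx = np.arange(s.size)[block_end]
    block_of = np.searchsorted(end_idx, np.arange(s.size))
    precision = precision[end_idx[block_of]]
    recall = tp / tp[-1]
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def confusion_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    single_class: str = "raise",
) -> tuple[float, float, float]:
    """(F1, accuracy, MCC) from the 2x2 table at ``score >= threshold``.

    MCC needs both classes present; with ``single_class="zero"`` a 0 is
    returned instead of an error.  A zero denominator factor also yields
    MCC = 0 by convention (logged).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        if single_class == "zero":
            logger.warning("single-class labels; MCC undefined, returning 0")
        else:
            raise ValueError("labels contain a single class; MCC undefined")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.debug("MCC denominator zero; returning 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return float(f1), float(acc), float(mcc)


def best_f1_threshold(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """Sweep all distinct scores; return (threshold, F1) maximizing F1.

    Vectorized over the descending sweep where the threshold equals each
    distinct score in turn (prediction rule ``score >= threshold``).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tp = np.cumsum(y)
    n_pos = int(tp[-1])
    block_end = np.ones(s.size, dtype=bool)
    block_end[:-1] = s[:-1] != s[1:]
    idx = np.nonzero(block_end)[0]
    tp_b = tp[idx]
    predicted_pos = idx + 1
    f1 = 2 * tp_b / (predicted_pos + n_pos)  # denominator >= 1 always
    best = int(np.argmax(f1))
    return float(s[idx[best]]), float(f1[best])


def _fold_weights(y_fold: np.ndarray, weights: WeightMatrix) -> WeightMatrix:
    if weights.unobserved is None:
        raise ValueError(
            "LOOCV needs unobserved-entry weights; build the WeightMatrix "
            "with build_weight_matrix or set .unobserved explicitly"
        )
    return WeightMatrix(
        w=np.where(y_fold == 1, 1.0, weights.unobserved),
        unobserved=weights.unobserved,
    )


def _default_scorer(sim: SimilarityMatrix, cfg: TrainConfig) -> Scorer:
    def score(assoc_fold: AssociationMatrix, weights_fold: WeightMatrix) -> np.ndarray:
        factors, _ = train(assoc_fold, weights_fold, sim, cfg)
        return predict_scores(factors, assoc_fold).scores

    return score


def _loocv(
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    sim: SimilarityMatrix,
    cfg: TrainConfig,
    protocol: str,
    scorer: Scorer | None,
    max_folds: int | None,
    fold_seed: int | None,
) -> tuple[list[FoldResult], MetricReport]:
    Y = assoc.y
    positions = np.argwhere(Y == 1)
    if len(positions) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    if max_folds is not None and max_folds < len(positions):
        rng = np.random.default_rng(cfg.seed if fold_seed is None else fold_seed)
        positions = positions[rng.choice(len(positions), size=max_folds, replace=False)]
    if scorer is None:
        scorer = _default_scorer(sim, cfg)

    folds: list[FoldResult] = []
    pos_scores: list[float] = []
    neg_scores: list[np.ndarray] = []
    for i, j in positions:
        y_fold = Y.copy()
        y_fold[i, j] = 0.0
        assoc_fold = AssociationMatrix(
            list(assoc.mirna_ids), list(assoc.disease_ids), y_fold
        )
        scores = scorer(assoc_fold, _fold_weights(y_fold, weights))
        if protocol == "global":
            cand = y_fold == 0
        else:
            cand = np.zeros_like(y_fold, dtype=bool)
            cand[:, j] = y_fold[:, j] == 0
        cand_other = cand.copy()
        cand_other[i, j] = False
        n_other = int(cand_other.sum())
        if n_other == 0:
            logger.warning(
                "skipping fold (%s, %s): no candidate negatives for its disease",
                assoc.mirna_ids[i],
                assoc.disease_ids[j],
            )
            continue
        s0 = float(scores[i, j])
        others = scores[cand_other]
        rank = 1.0 + float(np.sum(others > s0)) + 0.5 * float(np.sum(others == s0))
        folds.append(
            FoldResult(
                held_out_pair=(assoc.mirna_ids[i], assoc.disease_ids[j]),
                rank=rank,
                candidate_count=n_other,
                score=s0,
            )
        )
        pos_scores.append(s0)
        neg_scores.append(others)

    if not folds:
        raise ValueError("no usable folds")
    neg = np.concatenate(neg_scores)
    pos = np.asarray(pos_scores)
    pooled = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size, dtype=int), np.zeros(neg.size, dtype=int)])
    threshold, _ = best_f1_threshold(pooled, labels)
    f1, acc, mcc = confusion_metrics(pooled, labels, threshold, single_class="zero")
    report = MetricReport(
        auc=auc_from_ranks(pos, neg),
        aupr=average_precision(pooled, labels),
        f1=f1,
        acc=acc,
        mcc=mcc,
        threshold_used=threshold,
        protocol=protocol,
    )
    return folds, report


def global_loocv(
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    sim: SimilarityMatrix,
    cfg: TrainConfig,
    scorer: Scorer | None = None,
    max_folds: int | None = None,
    fold_seed: int | None = None,
) -> tuple[list[FoldResult], MetricReport]:
    """Leave-one-out over all known pairs; candidates span every disease.

    ``scorer`` may replace the default train-and-predict step (e.g. an
    oracle for testing).  ``max_folds`` subsamples folds reproducibly for
    large datasets.
    """
    return _loocv(assoc, weights, sim, cfg, "global", scorer, max_folds, fold_seed)


def local_loocv(
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    sim: SimilarityMatrix,
    cfg: TrainConfig,
    scorer: Scorer | None = None,
    max_folds: int | None = None,
    fold_seed: int | None = None,
) -> tuple[list[FoldResult], MetricReport]:
    """As :func:`global_loocv` but candidates are the held-out disease's column."""
    return _loocv(assoc, weights, sim, cfg, "local", scorer, max_folds, fold_seed)


def rank_candidates(
    scores: ScoreMatrix,
    assoc: AssociationMatrix,
    disease: str,
    top_n: int = 50,
) -> list[tuple[str, float]]:
    """Top candidate miRNAs (no known association) for a disease, best first.

    Ties are broken by miRNA id ascending so output is deterministic.
    """
    j = assoc.disease_index(disease)
    col = scores.scores[:, j]
    candidates = [
        (assoc.mirna_ids[i], float(col[i]))
        for i in range(len(assoc.mirna_ids))
        if assoc.y[i, j] == 0
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[:top_n]
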