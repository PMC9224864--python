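import numpy as np
import pytest

from mdmf.evaluation import (
    auc_from_ranks,
    average_precision,
    best_f1_threshold,
    confusion_metrics,
    global_loocv,
    local_loocv,
    rank_candidates,
)
from mdmf.factorization import ScoreMatrix, TrainConfig
from mdmf.io import AssociationMatrix, WeightMatrix
from mdmf.similarity import SimilarityMatrix


# ---------------------------------------------------------------- oracles
def brute_force_auc(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_confusion(scores, labels, threshold):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = 1 if s >= threshold else 0
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def oracle_scorer(full_y):
    """Scorer that returns the true full association matrix regardless of fold."""

    def score(assoc_fold, weights_fold):
        return full_y.astype(float)

    return score


# ---------------------------------------------------------------- metrics
class TestAuc:
    def test_perfect_separation(self):
        assert auc_from_ranks([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties_half(self):
        assert auc_from_ranks([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_mixed_pair_case(self):
        # pairs: (0.9 vs 0.8) win, (0.3 vs 0.8) loss -> 0.5
        assert auc_from_ranks([0.9, 0.3], [0.8]) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            auc_from_ranks([], [0.1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 100))
        m = int(rng.integers(2, 100))
        # quantized scores produce plenty of ties
        pos = np.round(rng.random(n), 1)
        neg = np.round(rng.random(m), 1)
        assert auc_from_ranks(pos, neg) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_cross_check_sklearn(self, seed):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        pos, neg = rng.random(30), rng.random(50)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(30), np.zeros(50)])
        assert auc_from_ranks(pos, neg) == pytest.approx(
            sklearn.roc_auc_score(labels, scores), abs=1e-12
        )


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_cross_check_sklearn(self, seed):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.random(n)  # distinct with probability 1
        labels = (rng.random(n) < 0.3).astype(int)
        if labels.sum() == 0:
            labels[0] = 1
        assert average_precision(scores, labels) == pytest.approx(
            sklearn.average_precision_score(labels, scores), abs=1e-12
        )

    def test_stepwise_hand_case(self):
        # sweep: ranks 1..4, positives at 1 and 3 -> AP = (1/1 + 2/3) / 2
        scores = [0.9, 0.7, 0.5, 0.3]
        labels = [1, 0, 1, 0]
        assert average_precision(scores, labels) == pytest.approx((1 + 2 / 3) / 2)


class TestConfusionMetrics:
    def test_perfect_separation(self):
        f1, acc, mcc = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert (f1, acc, mcc) == (1.0, 1.0, 1.0)

    def test_balanced_confusion(self):
        # TP=1, FP=1, TN=1, FN=1
        f1, acc, mcc = confusion_metrics([0.9, 0.9, 0.1, 0.1], [1, 0, 1, 0], 0.5)
        assert acc == 0.5 and f1 == 0.5 and mcc == 0.0

    def test_single_class_raises_unless_convention(self):
        with pytest.raises(ValueError, match="single class"):
            confusion_metrics([0.9, 0.1], [1, 1], 0.5)
        f1, acc, mcc = confusion_metrics([0.9, 0.1], [1, 1], 0.5, single_class="zero")
        assert mcc == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_count(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(50), 1)
        labels = (rng.random(50) < 0.4).astype(int)
        if labels.min() == labels.max():
            labels[:2] = [0, 1]
        thr = float(rng.choice(scores))
        tp, fp, tn, fn = brute_force_confusion(scores, labels, thr)
        f1, acc, mcc = confusion_metrics(scores, labels, thr)
        assert acc == pytest.approx((tp + tn) / 50)
        exp_f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        assert f1 == pytest.approx(exp_f1)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        exp_mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
        assert mcc == pytest.approx(exp_mcc)

    @pytest.mark.parametrize("seed", range(5))
    def test_best_f1_threshold_matches_exhaustive_sweep(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(60), 1)
        labels = (rng.random(60) < 0.3).astype(int)
        if labels.sum() == 0:
            labels[0] = 1
        thr, f1 = best_f1_threshold(scores, labels)
        best = max(
            confusion_metrics(scores, labels, t, single_class="zero")[0]
            for t in np.unique(scores)
        )
        assert f1 == pytest.approx(best)
        assert confusion_metrics(scores, labels, thr, single_class="zero")[0] == pytest.approx(best)


# ---------------------------------------------------------------- LOOCV
def make_problem(toy_assoc):
    q = len(toy_assoc.disease_ids)
    weights = WeightMatrix(
        w=np.where(toy_assoc.y == 1, 1.0, 0.5),
        unobserved=np.full(toy_assoc.shape, 0.5),
    )
    sim = SimilarityMatrix(list(toy_assoc.disease_ids), np.eye(q), "integrated")
    return weights, sim


class TestLoocv:
    def test_oracle_scorer_gives_auc_one(self, toy_assoc):
        weights, sim = make_problem(toy_assoc)
        cfg = TrainConfig(k=2, max_epochs=1)
        for runner in (global_loocv, local_loocv):
            _, report = runner(
                toy_assoc, weights, sim, cfg, scorer=oracle_scorer(toy_assoc.y)
            )
            assert report.auc == 1.0

    def test_global_fold_ranks_hand_enumerated(self, toy_assoc):
        """Deterministic scorer: score = 10*i + j (row-major position).

        Holding out (m3, d3) (i=2, j=2, score 22): candidates are the 7
        zeros of the fold's training matrix; ranks count higher scores.
        """
        weights, sim = make_problem(toy_assoc)
        scores = np.array([[10 * i + j for j in range(3)] for i in range(3)], float)
        scorer = lambda a, w: scores
        folds, _ = global_loocv(
            toy_assoc, weights, sim, TrainConfig(k=2, max_epochs=1), scorer=scorer
        )
        by_pair = {f.held_out_pair: f for f in folds}
        # held out (m1, d1): score 0; 6 other zeros all score higher -> rank 7
        assert by_pair[("m1", "d1")].rank == 7
        assert by_pair[("m1", "d1")].candidate_count == 6
        # held out (m2, d2): score 11; other candidates score {1,2,10,12,20,21},
        # three of which are higher -> rank 4
        assert by_pair[("m2", "d2")].rank == 4
        # held out (m3, d3): score 22 is the global maximum -> rank 1
        assert by_pair[("m3", "d3")].rank == 1

    def test_local_fold_ranks_hand_enumerated(self, toy_assoc):
        weights, sim = make_problem(toy_assoc)
        scores = np.array([[10 * i + j for j in range(3)] for i in range(3)], float)
        scorer = lambda a, w: scores
        folds, _ = local_loocv(
            toy_assoc, weights, sim, TrainConfig(k=2, max_epochs=1), scorer=scorer
        )
        by_pair = {f.held_out_pair: f for f in folds}
        # column d1: held (m1,d1) score 0 vs zeros (m2,d1)=10, (m3,d1)=20 -> rank 3
        assert by_pair[("m1", "d1")].rank == 3
        assert by_pair[("m1", "d1")].candidate_count == 2
        # column d3: held (m3,d3)=22 vs (m1,d3)=2, (m2,d3)=12 -> rank 1
        assert by_pair[("m3", "d3")].rank == 1

    def test_single_disease_local_equals_global(self):
        y = np.array([[1.0], [0.0], [1.0], [0.0]])
        assoc = AssociationMatrix(["m1", "m2", "m3", "m4"], ["d1"], y)
        weights = WeightMatrix(w=np.where(y == 1, 1.0, 0.3), unobserved=np.full_like(y, 0.3))
        sim = SimilarityMatrix(["d1"], np.array([[1.0]]), "integrated")
        scorer = lambda a, w: np.arange(4, dtype=float).reshape(4, 1)
        cfg = TrainConfig(k=2, max_epochs=1)
        gf, _ = global_loocv(assoc, weights, sim, cfg, scorer=scorer)
        lf, _ = local_loocv(assoc, weights, sim, cfg, scorer=scorer)
        assert [(f.held_out_pair, f.rank) for f in gf] == [
            (f.held_out_pair, f.rank) for f in lf
        ]

    def test_retrained_loocv_deterministic(self, toy_assoc):
        weights, sim = make_problem(toy_assoc)
        cfg = TrainConfig(k=2, alpha=0.5, eta=0.05, max_epochs=50, seed=3)
        f1, r1 = global_loocv(toy_assoc, weights, sim, cfg)
        f2, r2 = global_loocv(toy_assoc, weights, sim, cfg)
        assert [(f.held_out_pair, f.rank, f.score) for f in f1] == [
            (f.held_out_pair, f.rank, f.score) for f in f2
        ]
        assert r1 == r2

    def test_too_few_associations_error(self):
        y = np.array([[1.0, 0.0]])
        assoc = AssociationMatrix(["m1"], ["d1", "d2"], y)
        weights = WeightMatrix(w=y, unobserved=np.zeros_like(y))
        sim = SimilarityMatrix(["d1", "d2"], np.eye(2), "integrated")
        with pytest.raises(ValueError, match="at least 2"):
            global_loocv(assoc, weights, sim, TrainConfig(k=2))

    def test_global_auc_invariant_to_disease_permutation(self, toy_assoc):
        weights, sim = make_problem(toy_assoc)
        scores = np.array([[10 * i + j for j in range(3)] for i in range(3)], float)
        cfg = TrainConfig(k=2, max_epochs=1)
        _, base = global_loocv(toy_assoc, weights, sim, cfg, scorer=lambda a, w: scores)
        perm = [2, 0, 1]
        assoc_p = AssociationMatrix(
            list(toy_assoc.mirna_ids),
            [toy_assoc.disease_ids[j] for j in perm],
            toy_assoc.y[:, perm],
        )
        weights_p = WeightMatrix(w=weights.w[:, perm], unobserved=weights.unobserved[:, perm])
        sim_p = SimilarityMatrix(
            list(assoc_p.disease_ids), sim.values[np.ix_(perm, perm)], "integrated"
        )
        _, permuted = global_loocv(
            assoc_p, weights_p, sim_p, cfg, scorer=lambda a, w: scores[:, perm]
        )
        assert permuted.auc == pytest.approx(base.auc)

    def test_oracle_beats_arbitrary_scorer_locally(self, toy_assoc):
        weights, sim = make_problem(toy_assoc)
        cfg = TrainConfig(k=2, max_epochs=1)
        _, oracle = local_loocv(
            toy_assoc, weights, sim, cfg, scorer=oracle_scorer(toy_assoc.y)
        )
        rng = np.random.default_rng(0)
        random_scores = rng.random(toy_assoc.shape)
        _, other = local_loocv(
            toy_assoc, weights, sim, cfg, scorer=lambda a, w: random_scores
        )
        assert oracle.auc >= other.auc


class TestRankCandidates:
    def make_scores(self, assoc, values):
        return ScoreMatrix(
            mirna_ids=list(assoc.mirna_ids),
            disease_ids=list(assoc.disease_ids),
            scores=np.asarray(values, dtype=float),
        )

    def test_ties_broken_by_id(self, toy_assoc):
        scores = self.make_scores(toy_assoc, np.zeros(toy_assoc.shape))
        out = rank_candidates(scores, toy_assoc, "d1", top_n=10)
        assert out == [("m2", 0.0), ("m3", 0.0)]

    def test_known_associations_excluded_and_top_n(self, toy_assoc):
        vals = np.arange(9, dtype=float).reshape(3, 3)
        scores = self.make_scores(toy_assoc, vals)
        out = rank_candidates(scores, toy_assoc, "d2", top_n=1)
        # column d2: m1 (score 1) and m3 (score 7) are candidates; m2 is known
        assert out == [("m3", 7.0)]

    def test_unknown_disease_errors(self, toy_assoc):
        scores = self.make_scores(toy_assoc, np.zeros(toy_assoc.shape))
        with pytest.raises(KeyError, match="dX"):
            rank_candidates(scores, toy_assoc, "dX")
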