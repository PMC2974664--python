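"""Confusion counts, Sen/Spe/Acc/MCC, ROC AUC, threshold scan and k-fold CV
against independent brute-force oracles."""

import math

import numpy as np
import pytest

from epiwin import (
    ConfusionCounts,
    SVMConfig,
    assemble_set,
    confusion,
    cross_validate,
    generate_all_patterns,
    metrics,
    roc_auc,
    threshold_scan,
)
from epiwin.evaluation import DEFAULT_THRESHOLDS


def loop_confusion(scores, labels, thr):
    """Independent per-item tally oracle."""
    tp = fp = tn = fn = 0
    for s, lab in zip(scores, labels):
        call = s >= thr
        if call and lab:
            tp += 1
        elif call and not lab:
            fp += 1
        elif not call and lab:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def pairwise_auc(scores, labels):
    """Exhaustive rank-pair oracle: (pairs won + half ties) / (pos * neg)."""
    pos = [s for s, lab in zip(scores, labels) if lab == 1]
    neg = [s for s, lab in zip(scores, labels) if lab == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_all_positive_above_threshold(self):
        c = confusion(np.ones(5), np.ones(5, dtype=int), 0.0)
        assert c == ConfusionCounts(TP=5, FP=0, TN=0, FN=0)

    def test_threshold_above_max_score_calls_nothing(self):
        c = confusion(np.array([0.1, 0.5]), np.array([1, 0]), 2.0)
        assert c.TP == 0 and c.FP == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        for thr in (-1.0, 0.0, float(scores[0]), 0.7):
            assert confusion(scores, labels, thr) == loop_confusion(scores, labels, thr)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ in length"):
            confusion(np.ones(3), np.ones(2, dtype=int), 0.0)


class TestMetrics:
    def test_perfect_classifier(self):
        row = metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (row.sen, row.spe, row.acc, row.mcc) == (100.0, 100.0, 100.0, 1.0)

    def test_chance_performance(self):
        row = metrics(ConfusionCounts(TP=25, FP=25, TN=25, FN=25))
        assert row.acc == 50.0 and row.mcc == 0.0

    def test_hand_computed_example(self):
        # Sen=100*3/4, Spe=100*2/4, Acc=100*5/8,
        # MCC=(3*2-2*1)/sqrt(4*4*5*3)=4/sqrt(240)
        row = metrics(ConfusionCounts(TP=3, FP=2, TN=2, FN=1))
        assert row.sen == pytest.approx(75.0)
        assert row.spe == pytest.approx(50.0)
        assert row.acc == pytest.approx(62.5)
        assert row.mcc == pytest.approx(4 / math.sqrt(240))

    def test_agrees_with_sklearn_mcc_on_random_counts(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(0)
        for _ in range(20):
            y_true = rng.integers(0, 2, 50)
            y_pred = rng.integers(0, 2, 50)
            c = ConfusionCounts(
                TP=int(((y_pred == 1) & (y_true == 1)).sum()),
                FP=int(((y_pred == 1) & (y_true == 0)).sum()),
                TN=int(((y_pred == 0) & (y_true == 0)).sum()),
                FN=int(((y_pred == 0) & (y_true == 1)).sum()),
            )
            expected = matthews_corrcoef(y_true, y_pred)
            assert metrics(c).mcc == pytest.approx(expected, abs=1e-12)

    def test_degenerate_denominator_flagged_as_zero(self):
        row = metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=0))
        assert row.mcc == 0.0 and row.mcc_degenerate

    def test_accuracy_is_prevalence_weighted_mix_of_sen_and_spe(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4).tolist()
            row = metrics(ConfusionCounts(tp, fp, tn, fn))
            prev = (tp + fn) / (tp + fp + tn + fn)
            assert row.acc == pytest.approx(prev * row.sen + (1 - prev) * row.spe)


class TestROC:
    def test_perfect_separation_gives_auc_1(self):
        assert roc_auc(np.array([1, 2, 3, -1, -2]), np.array([1, 1, 1, 0, 0])) == 1.0

    def test_independent_scores_give_chance_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.03

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, 60).astype(float)  # forces ties
        labels = rng.integers(0, 2, 60)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels))

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(np.exp(scores), labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.ones(3), np.ones(3, dtype=int))


class TestThresholdScan:
    def test_one_row_per_threshold(self):
        rng = np.random.default_rng(1)
        scores, labels = rng.normal(size=50), rng.integers(0, 2, 50)
        grid = np.round(np.arange(-1, 1.0001, 0.1), 10)
        result = threshold_scan(scores, labels, grid)
        assert len(result.rows) == 21

    def test_selected_row_minimizes_sen_spe_gap_exhaustively(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.normal(1, 1, 80), rng.normal(-1, 1, 80)])
        labels = np.array([1] * 80 + [0] * 80)
        result = threshold_scan(scores, labels, DEFAULT_THRESHOLDS)
        gap = abs(result.selected.sen - result.selected.spe)
        for row in result.rows.itertuples():
            assert gap <= abs(row.sen - row.spe) + 1e-12

    def test_symmetric_gaussians_select_the_crossover_threshold(self):
        """For two symmetric score distributions the Sen=Spe point is the
        midpoint between the class means."""
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(2, 1, 4000), rng.normal(-2, 1, 4000)])
        labels = np.array([1] * 4000 + [0] * 4000)
        result = threshold_scan(scores, labels, DEFAULT_THRESHOLDS)
        assert abs(result.selected.threshold - 0.0) <= 0.2


@pytest.fixture(scope="module")
def balanced_set(small_synthetic_set):
    pats = generate_all_patterns(small_synthetic_set, 9)
    return assemble_set(pats, "balanced", seed=5)


class TestCrossValidate:
    def test_every_pattern_tested_exactly_once_and_sizes_near_equal(
        self, balanced_set
    ):
        result = cross_validate(
            balanced_set, "cpp", 9, SVMConfig(gamma=0.01), k=5, seed=2
        )
        assert sum(result.fold_sizes) == len(balanced_set.patterns)
        assert max(result.fold_sizes) - min(result.fold_sizes) <= 1

    def test_antigen_level_split_keeps_antigens_whole(self, balanced_set):
        from epiwin.evaluation import _fold_assignment

        folds = _fold_assignment(balanced_set, 5, "antigen", seed=3)
        by_antigen = {}
        for p, f in zip(balanced_set.patterns, folds):
            by_antigen.setdefault(p.antigen_id, set()).add(int(f))
        assert all(len(v) == 1 for v in by_antigen.values())

    def test_equal_folds_make_mean_acc_equal_pooled_acc(self, small_synthetic_set):
        # 5 folds over a multiple-of-5 pattern count: exact equality holds
        pats = generate_all_patterns(small_synthetic_set, 9)
        pset = assemble_set(pats, "balanced", seed=8)
        n = len(pset.patterns) - len(pset.patterns) % 5
        pset.patterns = pset.patterns[:n]
        result = cross_validate(pset, "cpp", 9, SVMConfig(gamma=0.01), k=5, seed=2)
        assert result.mean_row.acc == pytest.approx(result.pooled_row.acc)

    def test_k_below_2_rejected(self, balanced_set):
        with pytest.raises(ValueError, match="k must be"):
            cross_validate(balanced_set, "cpp", 9, SVMConfig(), k=1)
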