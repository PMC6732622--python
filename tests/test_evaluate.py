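import math

import numpy as np
import pytest

import repolink as rl
from repolink import evaluate
from repolink.config import RunConfig


def brute_force_auc(scores, labels):
    """Pair-counting Mann-Whitney oracle with half-credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestSampleNegatives:
    def test_forced_outcome_2x2(self):
        assoc = rl.AssociationMatrix(["u0", "u1"], ["d0", "d1"], np.eye(2, dtype=int))
        ds = evaluate.sample_negatives(assoc, 0)
        assert sorted(ds.negatives) == [(0, 1), (1, 0)]

    def test_seeded_determinism(self, toy_assoc):
        a = evaluate.sample_negatives(toy_assoc, 42)
        b = evaluate.sample_negatives(toy_assoc, 42)
        assert a.negatives == b.negatives

    def test_no_overlap_no_duplicates(self, fixture_triple):
        assoc = fixture_triple[0]
        ds = evaluate.sample_negatives(assoc, 3)
        assert len(ds.negatives) == len(ds.positives)
        assert len(set(ds.negatives)) == len(ds.negatives)
        assert not set(ds.negatives) & set(ds.positives)

    def test_uniform_frequency_over_zero_cells(self):
        # 4x4 with 4 positives -> 12 zero cells, each drawn w.p. 4/12 per run
        A = np.eye(4, dtype=int)
        assoc = rl.AssociationMatrix(
            [f"u{i}" for i in range(4)], [f"d{j}" for j in range(4)], A
        )
        counts: dict[tuple[int, int], int] = {}
        n_runs = 10_000
        for seed in range(n_runs):
            for cell in evaluate.sample_negatives(assoc, seed).negatives:
                counts[cell] = counts.get(cell, 0) + 1
        p = 4 / 12
        sigma = math.sqrt(n_runs * p * (1 - p))
        assert len(counts) == 12
        for c in counts.values():
            assert abs(c - n_runs * p) < 3 * sigma

    def test_insufficient_zero_cells(self):
        A = np.ones((2, 2), dtype=int)
        A[0, 0] = 0
        assoc = rl.AssociationMatrix(["u0", "u1"], ["d0", "d1"], A)
        with pytest.raises(ValueError):
            evaluate.sample_negatives(assoc, 0)


class TestAssignFolds:
    @staticmethod
    def _dataset(n_pos, n_neg):
        pos = [(i, 0) for i in range(n_pos)]
        neg = [(i, 1) for i in range(n_neg)]
        return evaluate.PairDataset(pos, neg)

    def test_exact_division(self):
        ds = evaluate.assign_folds(self._dataset(10, 10), 10, 0)
        sizes = np.bincount(list(ds.fold_assignment.values()))[1:]
        assert (sizes == 2).all()

    def test_pigeonhole_23_samples(self):
        ds = evaluate.assign_folds(self._dataset(12, 11), 10, 1)
        sizes = sorted(np.bincount(list(ds.fold_assignment.values()))[1:])
        assert sizes == [2] * 7 + [3] * 3

    def test_partition_and_stratification(self, fixture_triple):
        assoc = fixture_triple[0]
        ds = evaluate.sample_negatives(assoc, 5)
        ds = evaluate.assign_folds(ds, 10, 5)
        samples = ds.samples()
        assert sorted(ds.fold_assignment.keys()) == sorted(samples)
        sizes = np.bincount([ds.fold_of(s) for s in samples])[1:]
        assert sizes.max() - sizes.min() <= 1
        # stratified: per-fold positive counts also differ by at most one
        pos_sizes = np.bincount(
            [ds.fold_of(s) for s in samples if s[2] == 1], minlength=11
        )[1:]
        assert pos_sizes.max() - pos_sizes.min() <= 1

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            evaluate.assign_folds(self._dataset(2, 2), 5, 0)


class TestClassifiers:
    @staticmethod
    def _toy(seed=0, n=10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] > 0).astype(int)
        if y.min() == y.max():  # force both classes
            y[0] = 1 - y[0]
        return X, y

    def test_rf_memorizes_training_set(self):
        X, y = self._toy()
        clf = evaluate.train_random_forest(X, y, RunConfig(rng_seed=0))
        scores = evaluate.predict_scores(clf, X)
        assert ((scores >= 0.5).astype(int) == y).all()
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_single_tree_votes_are_binary(self):
        X, y = self._toy(1)
        clf = evaluate.train_random_forest(X, y, RunConfig(n_trees=1, rng_seed=0))
        assert set(np.unique(evaluate.predict_scores(clf, X))) <= {0.0, 1.0}

    def test_rf_single_class_rejected(self):
        X, _ = self._toy()
        with pytest.raises(ValueError):
            evaluate.train_random_forest(X, np.ones(len(X)), RunConfig())

    def test_svm_separable_toy_and_interface(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        clf = evaluate.train_svm(X, y, RunConfig(rng_seed=0))
        scores = evaluate.predict_scores(clf, X)
        assert ((scores >= 0) & (scores <= 1)).all()
        assert ((scores >= 0.5).astype(int) == y).all()
        with pytest.raises(ValueError):
            evaluate.train_svm(X, np.zeros(40), RunConfig())


class TestConfusionAndMetrics:
    def test_simple_tally(self):
        c = evaluate.confusion([0.9, 0.1], [1, 0], 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_threshold_boundary_is_positive(self):
        c = evaluate.confusion([0.5, 0.5], [1, 0], 0.5)
        assert c.TP == 1 and c.FP == 1

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(7)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        c = evaluate.confusion(scores, labels, 0.4)
        tp = sum(1 for s, y in zip(scores, labels) if s >= 0.4 and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= 0.4 and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s < 0.4 and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < 0.4 and y == 0)
        assert (c.TP, c.FP, c.FN, c.TN) == (tp, fp, fn, tn)

    def test_hand_metrics(self):
        m = evaluate.metrics(evaluate.ConfusionCounts(TP=9, FP=1, TN=9, FN=1))
        assert m.accuracy == m.precision == m.recall == m.f1 == pytest.approx(0.9)

    def test_undefined_metrics_are_nan_not_zero(self):
        m = evaluate.metrics(evaluate.ConfusionCounts(TP=0, FP=0, TN=10, FN=0))
        assert m.accuracy == 1.0
        assert math.isnan(m.precision) and math.isnan(m.recall) and math.isnan(m.f1)

    def test_f1_is_harmonic_mean_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            c = evaluate.ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            if c.total == 0:
                continue
            m = evaluate.metrics(c)
            if not (math.isnan(m.precision) or math.isnan(m.recall)):
                if m.precision + m.recall > 0:
                    hm = 2 * m.precision * m.recall / (m.precision + m.recall)
                    assert m.f1 == pytest.approx(hm, abs=1e-12)
            assert m.accuracy == pytest.approx((tp + tn) / c.total)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = evaluate.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(5000)
        labels = rng.integers(0, 2, 5000)
        _, auc = evaluate.roc_auc(scores, labels)
        assert 0.45 < auc < 0.55

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        _, auc = evaluate.roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate.roc_auc([0.1, 0.9], [1, 1])


class TestScoreDistribution:
    def test_concentrated_positives(self):
        out = evaluate.score_distribution([0.95, 0.95, 0.2], [1, 1, 0])
        assert out[1][9] == 1.0
        assert out[0][2] == 1.0

    def test_proportions_sum_to_one_and_match_histogram(self):
        rng = np.random.default_rng(3)
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        out = evaluate.score_distribution(scores, labels)
        for label in (0, 1):
            assert out[label].sum() == pytest.approx(1.0)
            cls = scores[labels == label]
            expected, _ = np.histogram(cls, bins=np.linspace(0, 1, 11))
            np.testing.assert_allclose(out[label], expected / len(cls))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate.score_distribution([], [])


@pytest.fixture(scope="module")
def small_report(small_triple):
    assoc, fp, sem, _ = small_triple
    cfg = RunConfig(
        rng_seed=0, cv_folds=5, ae_hidden_dim=16, ae_epochs=60,
        fc_width=32, refiner_epochs=30, n_trees=50,
    )
    return evaluate.cross_validate(assoc, fp, sem, cfg), cfg, small_triple


class TestCrossValidate:
    def test_report_shape_and_mean_bounds(self, small_report):
        report, cfg, _ = small_report
        assert len(report.folds) == cfg.cv_folds
        accs = [f.accuracy for f in report.folds]
        assert min(accs) <= report.mean("accuracy") <= max(accs)
        assert min(report.fold_aucs) <= report.mean_auc <= max(report.fold_aucs)

    def test_deterministic_under_config(self, small_report):
        report, cfg, triple = small_report
        assoc, fp, sem, _ = triple
        again = evaluate.cross_validate(assoc, fp, sem, cfg)
        assert report.fold_aucs == again.fold_aucs
        np.testing.assert_array_equal(report.pooled_scores, again.pooled_scores)

    def test_planted_structure_recovered(self, small_report):
        report, _, _ = small_report
        assert report.mean_auc > 0.8


class TestRanking:
    def test_output_complete_and_sorted(self, small_triple):
        assoc, fp, sem, _ = small_triple
        cfg = RunConfig(
            rng_seed=1, ae_hidden_dim=16, ae_epochs=60, fc_width=32,
            refiner_epochs=30, n_trees=50,
        )
        ranking = evaluate.rank_drugs_for_disease(
            assoc.disease_ids[0], assoc, fp, sem, cfg
        )
        assert len(ranking.ranked) == assoc.n_drugs
        assert sorted(d for d, _ in ranking.ranked) == sorted(assoc.drug_ids)
        keys = [(-s, d) for d, s in ranking.ranked]
        assert keys == sorted(keys)
        assert all(0 <= s <= 1 for _, s in ranking.ranked)

    def test_no_leakage_of_removed_column(self, small_triple):
        assoc, fp, sem, _ = small_triple
        target = assoc.disease_ids[2]
        cfg = RunConfig(
            rng_seed=2, ae_hidden_dim=16, ae_epochs=60, fc_width=32,
            refiner_epochs=30, n_trees=50,
        )
        r1 = evaluate.rank_drugs_for_disease(target, assoc, fp, sem, cfg)
        # pre-zero the column: ranking must be identical
        A = assoc.A.copy()
        A[:, 2] = 0
        pre = rl.AssociationMatrix(list(assoc.drug_ids), list(assoc.disease_ids), A)
        r2 = evaluate.rank_drugs_for_disease(target, pre, fp, sem, cfg)
        assert r1.ranked == r2.ranked

    def test_unknown_disease_rejected(self, small_triple):
        assoc, fp, sem, _ = small_triple
        with pytest.raises(KeyError):
            evaluate.rank_drugs_for_disease("nope", assoc, fp, sem)
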