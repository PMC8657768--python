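"""Dataset assembly, classifiers, metrics and cross-validation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ppirank.classify import (
    LabeledDataset,
    LogisticParams,
    assemble_dataset,
    auc_trapezoid,
    confusion_metrics,
    cross_validate,
    fit_classifier,
    logistic_fit,
    logistic_predict_proba,
    roc_pr_curves,
)
from ppirank.embedding import EmbeddingMatrix
from ppirank.network_io import GeneLabelSet


def toy_embedding(n, d=4, seed=0):
    rng = np.random.Generator(np.random.PCG64(seed))
    return EmbeddingMatrix(
        ids=tuple(f"g{i}" for i in range(n)), vectors=rng.normal(size=(n, d))
    )


def blob_dataset(n_per_class=60, d=2, gap=4.0, seed=0):
    rng = np.random.Generator(np.random.PCG64(seed))
    x = np.vstack(
        [
            rng.normal(loc=+gap / 2, size=(n_per_class, d)),
            rng.normal(loc=-gap / 2, size=(n_per_class, d)),
        ]
    )
    y = np.r_[np.ones(n_per_class, dtype=np.int64), np.zeros(n_per_class, dtype=np.int64)]
    ids = tuple(f"s{i}" for i in range(2 * n_per_class))
    return LabeledDataset(features=x, labels=y, gene_ids=ids)


class TestAssembleDataset:
    def test_balanced_size(self):
        emb = toy_embedding(40)
        pos = GeneLabelSet(frozenset(f"g{i}" for i in range(10)))
        data = assemble_dataset(emb, pos, seed=1)
        assert data.n == 20
        assert data.labels.sum() == 10

    def test_single_positive(self):
        emb = toy_embedding(11)
        data = assemble_dataset(emb, GeneLabelSet(frozenset({"g0"})), seed=0)
        assert data.n == 2 and set(data.labels) == {0, 1}

    def test_seed_controls_negative_draw(self):
        emb = toy_embedding(1000)
        pos = GeneLabelSet(frozenset(f"g{i}" for i in range(50)))
        a = assemble_dataset(emb, pos, seed=3)
        b = assemble_dataset(emb, pos, seed=3)
        c = assemble_dataset(emb, pos, seed=4)
        assert a.gene_ids == b.gene_ids
        assert a.gene_ids != c.gene_ids  # overwhelming probability

    def test_too_few_unlabeled_raises(self):
        emb = toy_embedding(10)
        pos = GeneLabelSet(frozenset(f"g{i}" for i in range(8)))
        with pytest.raises(ValueError):
            assemble_dataset(emb, pos)


class TestLogistic:
    def test_zero_params_give_half(self):
        p = LogisticParams(w=np.zeros(3), b=0.0)
        assert logistic_predict_proba(p, np.ones((1, 3)))[0] == pytest.approx(0.5)

    def test_log_odds_closed_form(self):
        # w.x + b = ln 3  ->  p = 0.75
        p = LogisticParams(w=np.array([np.log(3.0)]), b=0.0)
        assert logistic_predict_proba(p, np.array([[1.0]]))[0] == pytest.approx(0.75)

    def test_separable_blobs_reach_high_accuracy(self):
        data = blob_dataset(seed=2)
        params = logistic_fit(data.features, data.labels)
        pred = logistic_predict_proba(params, data.features) >= 0.5
        assert np.mean(pred == data.labels) >= 0.98


@pytest.mark.filterwarnings("ignore::FutureWarning")
class TestFitClassifier:
    @pytest.mark.parametrize("kind", ["svm", "logistic", "random_forest"])
    def test_trivially_separable_single_feature(self, kind):
        x = np.array([[1.0]] * 20 + [[-1.0]] * 20)
        y = np.r_[np.ones(20, dtype=np.int64), np.zeros(20, dtype=np.int64)]
        data = LabeledDataset(
            features=x, labels=y, gene_ids=tuple(f"s{i}" for i in range(40))
        )
        model = fit_classifier(kind, data, seed=0)
        scores = model.score_samples(x)
        assert np.all((scores >= 0) & (scores <= 1))
        assert np.mean((scores >= 0.5) == y) == 1.0

    def test_svm_calibration_preserves_rank_order(self):
        data = blob_dataset(seed=3)
        model = fit_classifier("svm", data, seed=0)
        scores = model.score_samples(data.features)
        decision = model.est.decision_function(data.features)
        assert sps.spearmanr(scores, decision).statistic == pytest.approx(1.0)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            fit_classifier("perceptron", blob_dataset())


class TestConfusionMetrics:
    def test_precision_example(self):
        assert confusion_metrics(tp=3, tn=0, fp=1, fn=0)["precision"] == pytest.approx(0.75)

    def test_f1_equals_rate_when_precision_equals_recall(self):
        m = confusion_metrics(tp=6, tn=10, fp=2, fn=2)  # precision = recall = 0.75
        assert m["precision"] == m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_hand_computed_table(self):
        m = confusion_metrics(tp=50, tn=30, fp=10, fn=10)
        assert m["acc"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(5 / 6)
        assert m["fpr"] == pytest.approx(0.25)

    def test_zero_denominators_are_nan_not_zero(self):
        m = confusion_metrics(tp=0, tn=5, fp=0, fn=0)
        assert np.isnan(m["precision"]) and np.isnan(m["recall"]) and np.isnan(m["f1"])
        assert m["acc"] == pytest.approx(1.0)


def brute_force_roc(scores, labels):
    """Independent operating-point enumeration over all distinct thresholds."""
    pts = [(0.0, 0.0)]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    for t in sorted(set(scores), reverse=True):
        pred = [s >= t for s in scores]
        tp = sum(p and y for p, y in zip(pred, labels))
        fp = sum(p and not y for p, y in zip(pred, labels))
        pts.append((fp / n_neg, tp / n_pos))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    # dedupe consecutive repeats (e.g. the (0,0) start)
    out = [pts[0]]
    for p in pts[1:]:
        if p != out[-1]:
            out.append(p)
    return out


class TestCurvesAndAUC:
    def test_perfect_separator_passes_through_corner(self):
        roc, _ = roc_pr_curves([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any((x, y) == (0.0, 1.0) for x, y in roc)

    def test_constant_scores_give_diagonal(self):
        roc, _ = roc_pr_curves([0.5] * 6, [1, 0, 1, 0, 1, 0])
        np.testing.assert_array_equal(roc, [[0, 0], [1, 1]])
        assert auc_trapezoid(roc) == pytest.approx(0.5)

    def test_matches_brute_force_threshold_enumeration(self, rng):
        scores = rng.random(20).round(1)  # force ties
        labels = (rng.random(20) < 0.5).astype(int)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        roc, _ = roc_pr_curves(scores, labels)
        expected = brute_force_roc(list(scores), list(labels))
        np.testing.assert_allclose(roc, expected, atol=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_pr_curves([0.1, 0.9], [1, 1])

    def test_diagonal_and_perfect_areas(self):
        assert auc_trapezoid(np.array([[0, 0], [1, 1]])) == pytest.approx(0.5)
        assert auc_trapezoid(np.array([[0, 0], [0, 1], [1, 1]])) == pytest.approx(1.0)

    def test_unsorted_x_raises(self):
        with pytest.raises(ValueError):
            auc_trapezoid(np.array([[0.5, 0.1], [0.2, 0.9]]))

    def test_auroc_equals_mann_whitney_statistic(self, rng):
        scores = rng.permutation(200) / 200.0  # tie-free
        labels = (rng.random(200) < 0.4).astype(int)
        roc, _ = roc_pr_curves(scores, labels)
        auc = auc_trapezoid(roc)
        n1, n0 = labels.sum(), (1 - labels).sum()
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / (n1 * n0), abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_auroc_antisymmetry_under_score_negation(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        scores = rng.permutation(50) / 50.0
        labels = np.r_[np.ones(20, dtype=int), np.zeros(30, dtype=int)]
        auc_fwd = auc_trapezoid(roc_pr_curves(scores, labels)[0])
        auc_rev = auc_trapezoid(roc_pr_curves(-scores, labels)[0])
        assert auc_fwd + auc_rev == pytest.approx(1.0, abs=1e-12)


@pytest.mark.filterwarnings("ignore::FutureWarning")
class TestCrossValidate:
    def test_metrics_in_unit_interval_and_reported_per_fold(self):
        data = blob_dataset(seed=5)
        report = cross_validate(data, kind="logistic", k=5, seed=0)
        assert len(report.folds) == 5
        for fold in report.folds:
            for v in fold.values():
                assert 0.0 <= v <= 1.0
        for key, v in report.mean.items():
            assert v == pytest.approx(np.mean([f[key] for f in report.folds]))

    def test_perfectly_separable_data_scores_auroc_one(self):
        data = blob_dataset(gap=10.0, seed=6)
        report = cross_validate(data, kind="logistic", k=5, seed=0)
        assert report.mean["auroc"] == pytest.approx(1.0)

    def test_shuffled_labels_give_chance_auroc(self):
        aurocs = []
        for seed in range(5):
            rng = np.random.Generator(np.random.PCG64(seed))
            data = blob_dataset(gap=4.0, seed=seed)
            y = rng.permutation(data.labels)
            shuffled = LabeledDataset(
                features=data.features, labels=y, gene_ids=data.gene_ids
            )
            report = cross_validate(shuffled, kind="logistic", k=5, seed=seed)
            aurocs.append(report.mean["auroc"])
        assert abs(np.mean(aurocs) - 0.5) <= 0.1

    def test_stratified_fold_balance(self):
        from sklearn.model_selection import StratifiedKFold

        data = blob_dataset(n_per_class=33, seed=7)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for _, test in skf.split(data.features, data.labels):
            fold_y = data.labels[test]
            assert abs(fold_y.sum() - (len(fold_y) - fold_y.sum())) <= 1
            seen.extend(test)
        assert sorted(seen) == list(range(data.n))
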