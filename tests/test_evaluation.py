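"""SVM-kappa separability, silhouette cluster counts, chi-square comparisons."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from neurotsne import (
    cluster_count,
    cohens_kappa,
    compare_methods,
    evaluate_embedding,
    svm_separability,
)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_hand_arithmetic_confusion_table(self):
        # TP=40, FN=10, FP=10, TN=40: p_o = 0.8, p_e = 0.5, kappa = 0.6
        truth = np.repeat([1, 0], 50)
        pred = np.concatenate([
            np.ones(40), np.zeros(10),  # truth 1
            np.ones(10), np.zeros(40),  # truth 0
        ])
        assert cohens_kappa(truth, pred) == pytest.approx(0.6)

    def test_constant_prediction_on_balanced_truth_is_chance(self):
        truth = np.repeat([0, 1], 30)
        assert cohens_kappa(truth, np.zeros(60)) == pytest.approx(0.0)

    def test_both_constant_returns_zero(self):
        assert cohens_kappa(np.zeros(10), np.zeros(10)) == 0.0

    def test_symmetric_under_label_swap(self, rng):
        truth = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        assert cohens_kappa(truth, pred) == pytest.approx(
            cohens_kappa(1 - truth, 1 - pred)
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        truth = rng.integers(0, 3, 500)
        pred = rng.integers(0, 3, 500)
        assert cohens_kappa(truth, pred) == pytest.approx(
            cohen_kappa_score(truth, pred), abs=1e-12
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cohens_kappa([], [])


class TestSvmSeparability:
    def test_disjoint_clusters_perfect_for_both_kernels(self, rng):
        a = rng.normal(0.0, 0.05, (50, 2))
        b = rng.normal(1.0, 0.05, (50, 2))
        emb = np.concatenate([a, b])
        labels = np.repeat([0, 1], 50)
        for kernel in ("linear", "rbf"):
            assert svm_separability(emb, labels, emb, labels, kernel) == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        emb = rng.standard_normal((1000, 2))
        labels = rng.integers(0, 2, 1000)
        k = svm_separability(emb, labels, emb, labels, kernel="rbf")
        assert abs(k) < 0.1

    def test_radially_nested_classes_need_rbf(self, rng):
        # a cluster centered inside a surrounding ring: rotational symmetry
        # defeats any linear rule (a half-plane cut cannot isolate the
        # center class), while an RBF boundary separates them cleanly
        theta = rng.uniform(0, 2 * np.pi, 300)
        ring = np.c_[np.cos(theta), np.sin(theta)] * rng.normal(3.0, 0.05, 300)[:, None]
        blob = rng.normal(0, 0.2, (100, 2))
        emb = np.concatenate([ring, blob])
        labels = np.repeat([0, 1], [300, 100])
        assert svm_separability(emb, labels, emb, labels, "rbf") >= 0.9
        assert svm_separability(emb, labels, emb, labels, "linear") <= 0.1

    def test_single_class_fit_rejected(self, rng):
        emb = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="two classes"):
            svm_separability(emb, np.zeros(10), emb, np.zeros(10))


class TestClusterCount:
    def test_three_separated_blobs_recovered_across_seeds(self, rng):
        centers = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]])
        pts = np.concatenate(
            [c + rng.normal(0, 0.05, (100, 2)) for c in centers]
        )
        for seed in range(10):
            C, curve = cluster_count(pts, k_max=10, seed=seed)
            assert C == 3
        assert curve[3] > curve[2] and curve[3] > curve[4]

    def test_single_blob_low_silhouette_at_k2(self, rng):
        pts = rng.standard_normal((300, 2))
        C, curve = cluster_count(pts, k_max=10, seed=0)
        assert max(curve.values()) < 0.6
        assert C == max(range(2, 11), key=lambda k: (curve[k], -k))

    def test_duplicating_points_leaves_count_unchanged(self, rng):
        centers = np.array([[0.0, 0.0], [2.0, 0.0]])
        pts = np.concatenate([c + rng.normal(0, 0.05, (60, 2)) for c in centers])
        C1, _ = cluster_count(pts, k_max=8, seed=1)
        C2, _ = cluster_count(np.concatenate([pts, pts]), k_max=8, seed=1)
        assert C1 == C2 == 2

    def test_rigid_motion_invariance(self, rng):
        pts = np.concatenate([
            rng.normal(0, 0.05, (80, 2)),
            rng.normal(0, 0.05, (80, 2)) + [3.0, 1.0],
            rng.normal(0, 0.05, (80, 2)) + [0.0, 4.0],
        ])
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        C1, _ = cluster_count(pts, k_max=8, seed=2)
        C2, _ = cluster_count(pts @ R.T + [10.0, -5.0], k_max=8, seed=2)
        assert C1 == C2

    def test_too_few_points_restricts_k_max(self, rng):
        pts = rng.standard_normal((20, 2))
        with pytest.warns(UserWarning, match="restricting k_max"):
            C, curve = cluster_count(pts, k_max=50, seed=0)
        assert max(curve) == 19


class TestCompareMethods:
    def test_identical_predictions_statistic_zero(self, rng):
        truth = rng.integers(0, 2, 100)
        pred = rng.integers(0, 2, 100)
        res = compare_methods({"a": pred, "b": pred, "c": pred}, truth)
        assert res["omnibus"]["statistic"] == 0.0
        assert res["omnibus"]["p"] == 1.0
        assert res["posthoc"] == {}

    def test_matches_textbook_two_by_two(self):
        truth = np.zeros(100)
        pred_a = np.concatenate([np.zeros(90), np.ones(10)])  # 90 correct
        pred_b = np.concatenate([np.zeros(50), np.ones(50)])  # 50 correct
        res = compare_methods({"a": pred_a, "b": pred_b}, truth)
        table = np.array([[90, 10], [50, 50]])
        expected = chi2_contingency(table, correction=False)[0]
        # hand computation of sum((O-E)^2/E) on the same table
        row, col, n = table.sum(1), table.sum(0), table.sum()
        E = np.outer(row, col) / n
        assert expected == pytest.approx(((table - E) ** 2 / E).sum())
        assert res["omnibus"]["statistic"] == pytest.approx(expected)

    def test_bonferroni_doubles_posthoc_p(self):
        truth = np.zeros(100)
        preds = {
            "best": np.concatenate([np.zeros(95), np.ones(5)]),
            "mid": np.concatenate([np.zeros(60), np.ones(40)]),
            "worst": np.concatenate([np.zeros(50), np.ones(50)]),
        }
        res = compare_methods(preds, truth)
        assert res["omnibus"]["p"] < 0.05
        assert len(res["posthoc"]) == 2
        for entry in res["posthoc"].values():
            assert entry["p_adjusted"] == pytest.approx(
                min(1.0, 2 * entry["p_raw"])
            )
            assert entry["p_adjusted"] >= entry["p_raw"]

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_methods({"a": np.zeros(5), "b": np.zeros(6)}, np.zeros(5))


class TestEvaluateEmbedding:
    def test_full_report_on_separable_data(self, rng):
        train = np.concatenate([
            rng.normal(0, 0.05, (60, 2)), rng.normal(1.0, 0.05, (60, 2))
        ])
        labels = np.repeat([0, 1], 60)
        report = evaluate_embedding(train, labels, k_max=6, seed=0)
        assert report.kappa["rbf_train"] == 1.0
        assert report.kappa["linear_train"] == 1.0
        assert report.cluster_count["train"] == 2
        assert set(report.silhouette_curve["train"]) == set(range(2, 7))
        d = report.to_dict()
        assert "kappa" in d and "cluster_count" in d

    def test_train_fit_generalization_direction(self, rng):
        # on noisy data, training-split kappa >= test-split kappa on average
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            emb = r.standard_normal((200, 2))
            labels = (emb[:, 0] + r.normal(0, 1.5, 200) > 0).astype(int)
            tr, te = slice(0, 100), slice(100, 200)
            if len(np.unique(labels[tr])) < 2:
                continue
            k_tr = svm_separability(emb[tr], labels[tr], emb[tr], labels[tr], "rbf")
            k_te = svm_separability(emb[tr], labels[tr], emb[te], labels[te], "rbf")
            diffs.append(k_tr - k_te)
        assert np.mean(diffs) > 0
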