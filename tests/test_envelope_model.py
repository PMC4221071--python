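"""Envelope classifier diagnostics: OOB machinery, confusion-matrix
arithmetic, Cohen's kappa, rank-statistic AUC, permutation importance,
and sensitivity = specificity threshold selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from whitebark import envelope_model as em


def _blobs(n=500, sep=6.0, seed=0):
    """Two well-separated Gaussian classes in two covariates."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, (n // 2, 2))
    x1 = rng.normal(sep, 1.0, (n - n // 2, 2))
    X = np.vstack([x0, x1])
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestFitEnvelope:
    def test_wide_margin_classes_have_low_oob_error(self):
        X, y = _blobs(500, sep=6.0)
        model = em.fit_envelope(X, y, n_trees=150, seed=1)
        confusion = em.oob_confusion(model)
        assert confusion.error_rate_pct < 5.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(2)
        X, y = _blobs(600, sep=6.0, seed=2)
        y_shuffled = rng.permutation(y)
        model = em.fit_envelope(X, y_shuffled, n_trees=150, seed=2)
        assert abs(em.oob_confusion(model).error_rate_pct - 50.0) < 5.0

    def test_same_seed_reproduces_oob_probabilities(self):
        X, y = _blobs(200, seed=3)
        a = em.fit_envelope(X, y, n_trees=60, seed=9)
        b = em.fit_envelope(X, y, n_trees=60, seed=9)
        assert np.array_equal(a.oob_prob, b.oob_prob, equal_nan=True)

    def test_single_class_rejected(self):
        X = np.random.default_rng(4).normal(size=(50, 2))
        with pytest.raises(ValueError):
            em.fit_envelope(X, np.ones(50, int), n_trees=10, seed=0)

    def test_oob_auc_agrees_with_sklearn_forest(self):
        """Independent cross-check: scikit-learn's own random forest OOB
        decision function yields a similar OOB AUC on the same data."""
        X, y = _blobs(600, sep=2.5, seed=5)
        ours = em.fit_envelope(X, y, n_trees=300, seed=5)
        ok = ours.oob_defined
        auc_ours = em.roc_auc(ours.oob_prob[ok], y[ok])
        sk = RandomForestClassifier(
            n_estimators=300, oob_score=True, random_state=5, min_samples_leaf=1
        ).fit(X, y)
        auc_sk = em.roc_auc(sk.oob_decision_function_[:, 1], y)
        assert abs(auc_ours - auc_sk) < 0.03


class TestConfusionMatrix:
    def test_row_normalized_percentages(self):
        """Row-normalizing a 2x2 OOB table: predicted-presence row correct
        = tp/(tp+fp), predicted-absence row correct = tn/(fn+tn)."""
        c = em.ConfusionMatrix(tp=763, fp=169, fn=176, tn=1437)
        assert c.presence_row_pct_correct == pytest.approx(81.9, abs=0.05)
        assert c.absence_row_pct_correct == pytest.approx(89.1, abs=0.05)
        assert c.absence_row_pct_error == pytest.approx(10.9, abs=0.05)
        assert c.error_rate_pct == pytest.approx(100 * 345 / 2545, abs=1e-9)

    def test_perfect_classifier_diagonal(self):
        X, y = _blobs(300, sep=10.0, seed=6)
        model = em.fit_envelope(X, y, n_trees=100, seed=6)
        c = em.oob_confusion(model, threshold=0.5)
        assert c.fp == 0 and c.fn == 0

    def test_all_presence_threshold_kills_specificity(self):
        X, y = _blobs(200, seed=7)
        model = em.fit_envelope(X, y, n_trees=60, seed=7)
        c = em.oob_confusion(model, threshold=0.0)
        assert c.tnr == 0.0 and c.tpr == 1.0

    def test_kappa_hand_value(self):
        """Cohen's kappa of the fixed table (763, 169, 176, 1437) is
        0.7084 by direct evaluation of (po - pe)/(1 - pe)."""
        assert em.cohen_kappa(763, 169, 176, 1437) == pytest.approx(0.7084, abs=5e-4)


class TestPermutationImportance:
    def test_noise_covariate_near_zero(self):
        rng = np.random.default_rng(8)
        X, y = _blobs(500, sep=6.0, seed=8)
        X = np.column_stack([X, rng.standard_normal(len(y))])
        model = em.fit_envelope(X, y, n_trees=150, seed=8)
        imp = em.permutation_importance(model, X, n_repeats=8, seed=8)
        noise = imp.loc["x2"]
        assert abs(noise["importance"]) <= 2 * noise["sd"] / np.sqrt(8) + 5e-3

    def test_sole_informative_covariate_ranked_first(self):
        rng = np.random.default_rng(9)
        n = 600
        signal = rng.standard_normal(n)
        y = (signal + 0.3 * rng.standard_normal(n) > 0).astype(int)
        X = np.column_stack([rng.standard_normal(n), signal, rng.standard_normal(n)])
        model = em.fit_envelope(X, y, n_trees=150, seed=9)
        imp = em.permutation_importance(model, X, n_repeats=5, seed=9)
        assert imp.index[0] == "x1"
        assert imp.loc["x1", "importance"] > 5 * max(
            imp.loc["x0", "importance"], imp.loc["x2", "importance"], 1e-9
        )

    def test_constant_column_importance_exactly_zero(self):
        X, y = _blobs(200, seed=10)
        X = np.column_stack([X, np.full(len(y), 3.0)])
        model = em.fit_envelope(X, y, n_trees=60, seed=10)
        imp = em.permutation_importance(model, X, n_repeats=3, seed=10)
        assert imp.loc["x2", "importance"] == 0.0 and imp.loc["x2", "sd"] == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert em.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_pos_one_neg_brute_force_value(self):
        assert em.roc_auc([0.9, 0.8, 0.2, 0.4], [1, 1, 1, 0]) == pytest.approx(2 / 3)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(em.roc_auc(scores, labels) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            em.roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_rank_statistic_equals_pairwise_bruteforce(self, seed):
        """Oracle equivalence: the rank formula matches exhaustive
        pos-neg pair counting (ties worth one half) on small instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 17), n)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert em.roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)


class TestSelectThreshold:
    def test_separable_case_returns_midpoint(self):
        diag = em.select_threshold([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        assert diag.threshold == pytest.approx(0.5)
        assert diag.tpr_at_threshold == 1.0 and diag.tnr_at_threshold == 1.0

    def test_symmetric_errors_give_half(self):
        scores = [0.9, 0.8, 0.4, 0.6, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        diag = em.select_threshold(scores, labels)
        assert diag.threshold == pytest.approx(0.5)

    def test_equalization_and_tss_identity_on_random_scores(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(20, 300))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.clip(
                rng.random(n) * 0.5 + labels * rng.random(n) * 0.5, 0, 1
            )
            if np.unique(scores).size < 2:
                continue
            diag = em.select_threshold(scores, labels)
            assert abs(diag.tpr_at_threshold - diag.tnr_at_threshold) < 1e-6
            assert np.allclose(diag.tss, diag.tpr + diag.tnr - 1.0)
            tss_at_star = diag.tpr_at_threshold + diag.tnr_at_threshold - 1.0
            assert diag.max_tss >= tss_at_star - 1e-9

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            em.select_threshold([0.5, 0.5, 0.5], [1, 0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            em.select_threshold([0.1, 0.9], [1, 1])


class TestOnSyntheticStudy:
    def test_fitted_study_model_is_accurate_and_thresholdable(self, study, fitted):
        model = fitted["model"]
        labels = study["labels"]
        diag = em.select_threshold(model.oob_prob, labels)
        assert diag.auc > 0.9
        assert 0.0 < diag.threshold < 1.0
        assert 0.0 < diag.max_kappa <= 1.0
        assert 0.0 < diag.max_tss <= 1.0
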