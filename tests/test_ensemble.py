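"""Balanced-subset generation, ensemble averaging and the SMOTE comparator."""

import numpy as np
import pytest

from gliomics.ensemble import (
    EnsembleModel, load_model, make_balanced_subsets, predict, predict_proba,
    save_model, smote_oversample, train_ensemble,
)
from gliomics.evaluate import roc_auc
from gliomics.synthetic import gen_tabular_cohort


def _labels(n_pos, n_neg, seed=0):
    y = np.array([1] * n_pos + [0] * n_neg)
    np.random.default_rng(seed).shuffle(y)
    return y


class TestBalancedSubsets:
    def test_cohort_counts_give_188_sample_subsets(self):
        """94 mutated / 133 wild type: every subset is 94 + 94 samples."""
        y = _labels(94, 133)
        subsets = make_balanced_subsets(y, n_subsets=10, seed=0)
        assert len(subsets) == 10
        for sub in subsets:
            assert sub.indices.size == 188
            assert y[sub.indices].sum() == 94  # all minority samples
            assert set(np.flatnonzero(y == 1)) <= set(sub.indices.tolist())
            assert np.unique(sub.indices).size == 188  # without replacement

    def test_already_balanced_is_a_permutation(self):
        y = _labels(40, 40)
        (sub,) = make_balanced_subsets(y, n_subsets=1, seed=3)
        assert sorted(sub.indices.tolist()) == list(range(80))

    def test_majority_inclusion_frequency(self):
        """Each majority sample appears with frequency n_min/n_maj
        (Monte-Carlo over 2000 subsets, 3 SE tolerance)."""
        y = _labels(30, 90)
        subsets = make_balanced_subsets(y, n_subsets=2000, seed=7)
        maj = np.flatnonzero(y == 0)
        counts = np.zeros(y.size)
        for sub in subsets:
            counts[sub.indices] += 1
        p_hat = counts[maj] / 2000
        p = 30 / 90
        se = np.sqrt(p * (1 - p) / 2000)
        assert (np.abs(p_hat - p) < 3 * se + 1e-9).mean() > 0.97

    def test_swapped_classes_warn(self):
        y = _labels(60, 20)
        with pytest.warns(UserWarning, match="swapped"):
            subsets = make_balanced_subsets(y, n_subsets=2, seed=0)
        for sub in subsets:
            assert y[sub.indices].sum() == 20  # wild type kept whole


class TestEnsemble:
    def test_separable_data_training_auc_one(self):
        X, y = gen_tabular_cohort(120, 5, 1, 8.0, 2.0, seed=1)
        model = train_ensemble(X, y, n_subsets=5, seed=2,
                               hyperparams={"n_estimators": 50})
        probs = predict_proba(model, X)
        assert roc_auc(probs, y).auc == 1.0

    def test_prediction_is_exact_member_mean(self):
        X, y = gen_tabular_cohort(90, 6, 2, 1.0, 2.0, seed=3)
        model = train_ensemble(X, y, n_subsets=4, seed=5,
                               hyperparams={"n_estimators": 25})
        probs = predict_proba(model, X)
        member_probs = np.stack([
            m.predict_proba(X)[:, int(np.flatnonzero(m.classes_ == 1)[0])]
            for m in model.members])
        np.testing.assert_allclose(probs, member_probs.mean(axis=0), atol=1e-12)

    def test_member_order_irrelevant(self):
        X, y = gen_tabular_cohort(90, 6, 2, 1.0, 2.0, seed=3)
        model = train_ensemble(X, y, n_subsets=4, seed=5,
                               hyperparams={"n_estimators": 25})
        p0 = predict_proba(model, X)
        shuffled = EnsembleModel(
            members=model.members[::-1], classifier_kind=model.classifier_kind,
            feature_names=model.feature_names, n_subsets=model.n_subsets)
        np.testing.assert_allclose(p0, predict_proba(shuffled, X), atol=1e-15)

    def test_retrain_reproducible(self):
        X, y = gen_tabular_cohort(90, 6, 2, 1.0, 2.0, seed=3)
        a = train_ensemble(X, y, n_subsets=3, seed=9, hyperparams={"n_estimators": 25})
        b = train_ensemble(X, y, n_subsets=3, seed=9, hyperparams={"n_estimators": 25})
        np.testing.assert_array_equal(predict_proba(a, X), predict_proba(b, X))

    def test_xgboost_kind(self):
        X, y = gen_tabular_cohort(90, 6, 2, 2.0, 2.0, seed=3)
        model = train_ensemble(X, y, classifier_kind="xgboost", n_subsets=3,
                               seed=4, hyperparams={"n_estimators": 20})
        probs = predict_proba(model, X)
        assert ((probs >= 0) & (probs <= 1)).all()
        assert roc_auc(probs, y).auc > 0.9

    def test_feature_mismatch_errors(self):
        import pandas as pd
        X, y = gen_tabular_cohort(60, 4, 1, 1.0, 2.0, seed=0)
        Xdf = pd.DataFrame(X, columns=list("abcd"))
        model = train_ensemble(Xdf, y, n_subsets=2, seed=1,
                               hyperparams={"n_estimators": 10})
        with pytest.raises(ValueError, match="mismatch"):
            predict_proba(model, Xdf.rename(columns={"d": "z"}))

    def test_save_load_round_trip(self, tmp_path):
        X, y = gen_tabular_cohort(60, 4, 1, 1.5, 2.0, seed=0)
        model = train_ensemble(X, y, n_subsets=2, seed=1,
                               hyperparams={"n_estimators": 10})
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(predict_proba(model, X), predict_proba(back, X))
        np.testing.assert_array_equal(predict(model, X), predict(back, X))


class TestSMOTE:
    def test_counts_balanced(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        y = np.array([1] * 10 + [0] * 40)
        X2, y2 = smote_oversample(X, y, k_neighbors=5, seed=1)
        assert (y2 == 1).sum() == 40 and (y2 == 0).sum() == 40
        np.testing.assert_array_equal(X2[:50], X)

    def test_synthetic_points_on_minority_segments(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 2))
        y = np.array([1] * 8 + [0] * 32)
        X2, y2 = smote_oversample(X, y, k_neighbors=3, seed=2)
        minority = X[:8]
        for pt in X2[40:]:
            on_segment = False
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    t = float((pt - minority[i]) @ d) / denom
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(
                            minority[i] + t * d - pt) < 1e-9:
                        on_segment = True
            assert on_segment

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 2))
        y = np.repeat([0, 1], 10)
        X2, y2 = smote_oversample(X, y, k_neighbors=3, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_k_too_large_errors(self):
        X = np.zeros((12, 2))
        y = np.array([1] * 4 + [0] * 8)
        with pytest.raises(ValueError, match="k_neighbors"):
            smote_oversample(X, y, k_neighbors=4, seed=0)
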