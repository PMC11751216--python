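import logging

import numpy as np
import pytest
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from neurochoice.fuse_classify import (SMOTEConfig, align_windows,
                                       crossvalidate, default_base_learners,
                                       fit_stacking, fuse, predict_stacking,
                                       smote_balance)

FAST_BASES = [
    ("lr", LogisticRegression(max_iter=200)),
    ("dt", DecisionTreeClassifier(random_state=0)),
    ("dt2", DecisionTreeClassifier(random_state=1, max_depth=3)),
]


class TestAlign:
    def test_equal_counts_full_pairing(self):
        keys = [("S", 0)] * 7
        assert len(align_windows(keys, keys)) == 7

    def test_truncation_to_shorter_modality(self, caplog):
        with caplog.at_level(logging.WARNING):
            pairs = align_windows([("S", 0)] * 7, [("S", 0)] * 5)
        assert len(pairs) == 5
        assert "truncating" in caplog.text

    def test_disjoint_trials_empty(self, caplog):
        with caplog.at_level(logging.WARNING):
            pairs = align_windows([("S", 0)], [("S", 1)])
        assert pairs == []
        assert "dropped" in caplog.text

    def test_pairing_by_ordinal(self):
        eeg = [("S", 0), ("S", 1), ("S", 0)]
        et = [("S", 1), ("S", 0), ("S", 0)]
        pairs = align_windows(eeg, et)
        # trial 0: eeg indices [0, 2] pair with et [1, 2]; trial 1: [1]/[0]
        assert set(pairs) == {(0, 1), (2, 2), (1, 0)}


class TestFuse:
    def test_block_order_and_widths(self, rng):
        n = 6
        blocks = {
            "eeg_hand": rng.normal(size=(n, 361)),
            "et_hand": rng.normal(size=(n, 4)),
            "eeg_deep": rng.normal(size=(n, 14016)),
            "et_deep": rng.normal(size=(n, 2704)),
        }
        y = np.array([0, 1] * 3)
        subj = ["S"] * n
        deep = fuse(blocks, y, subj, "deep_only")
        assert deep.width == 16720
        assert [p[0] for p in deep.provenance] == ["eeg_deep", "et_deep"]
        hand = fuse(blocks, y, subj, "hand_only")
        assert hand.width == 365
        full = fuse(blocks, y, subj, "full")
        assert full.width == deep.width + hand.width
        assert [p[0] for p in full.provenance] == \
            ["eeg_deep", "et_deep", "eeg_hand", "et_hand"]

    def test_row_mismatch_rejected(self, rng):
        blocks = {"eeg_hand": rng.normal(size=(4, 3)),
                  "et_hand": rng.normal(size=(5, 2))}
        with pytest.raises(ValueError, match="misaligned"):
            fuse(blocks, np.zeros(4, int), ["S"] * 4, "hand_only")

    def test_nan_rejected(self):
        blocks = {"eeg_hand": np.array([[np.nan, 1.0]])}
        with pytest.raises(ValueError, match="NaN"):
            fuse(blocks, np.array([1]), ["S"], "hand_only")


class TestSMOTE:
    def test_exact_balance(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.array([1] * 10 + [0] * 30)
        Xb, yb = smote_balance(X, y, SMOTEConfig())
        assert (yb == 1).sum() == 30 and (yb == 0).sum() == 30
        np.testing.assert_array_equal(Xb[:40], X)  # originals untouched

    def test_identical_minority_points_reproduce_themselves(self, rng):
        X = np.vstack([np.tile([1.0, 2.0], (5, 1)), rng.normal(5, 1, (20, 2))])
        y = np.array([1] * 5 + [0] * 20)
        Xb, yb = smote_balance(X, y, SMOTEConfig())
        synth = Xb[25:]
        np.testing.assert_allclose(synth, np.tile([1.0, 2.0], (15, 1)))

    def test_synthetic_points_lie_on_minority_segments(self, rng):
        """2-D oracle: every synthetic point sits on a segment between two
        minority samples (distance to the nearest such segment ~ 0)."""
        X = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(6, 1, (30, 2))])
        y = np.array([1] * 8 + [0] * 30)
        Xb, yb = smote_balance(X, y, SMOTEConfig())
        minority = X[:8]
        for p in Xb[38:]:
            d = []
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    a, b = minority[i], minority[j]
                    t = np.clip(np.dot(p - a, b - a) /
                                max(np.dot(b - a, b - a), 1e-12), 0, 1)
                    d.append(np.linalg.norm(p - (a + t * (b - a))))
            assert min(d) < 1e-9

    def test_deterministic_under_random_state(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 8 + [0] * 22)
        a = smote_balance(X, y, SMOTEConfig(random_state=42))
        b = smote_balance(X, y, SMOTEConfig(random_state=42))
        np.testing.assert_array_equal(a[0], b[0])

    def test_minority_smaller_than_k_rejected(self, rng):
        X = rng.normal(size=(23, 3))
        y = np.array([1] * 3 + [0] * 20)
        with pytest.raises(ValueError, match="smaller k"):
            smote_balance(X, y, SMOTEConfig(k_neighbors=3))

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        Xb, yb = smote_balance(X, y, SMOTEConfig())
        assert len(Xb) == 20


def _blobs(rng, n=200, d=4, sep=6.0):
    X = rng.normal(size=(n, d))
    y = np.array([0, 1] * (n // 2))
    X[y == 1, 0] += sep
    return X, y


class TestStacking:
    def test_meta_feature_matrix_has_three_columns(self, rng):
        X, y = _blobs(rng, 60)
        model = fit_stacking(X, y, folds=3, base_learners=FAST_BASES)
        assert model.oof_Z.shape == (60, 3)

    def test_default_bases_are_the_prescribed_ensembles(self):
        bases = dict(default_base_learners())
        assert bases["rf"].n_estimators == 265
        assert bases["gb"].n_estimators == 89
        assert bases["xgb"].n_estimators == 300

    def test_separable_blobs_training_accuracy_one(self, rng):
        X, y = _blobs(rng, 200)
        model = fit_stacking(X, y, folds=5, seed=42, base_learners=FAST_BASES)
        pred, _ = predict_stacking(model, X)
        assert (pred == y).all()

    def test_constant_bases_give_constant_final(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0] * 20 + [1] * 20)
        bases = [("c", DummyClassifier(strategy="constant", constant=1))]
        model = fit_stacking(X, y, folds=4, base_learners=bases,
                             meta_learner="identity")
        pred, _ = predict_stacking(model, rng.normal(size=(10, 3)))
        assert (pred == 1).all()

    def test_single_base_identity_meta_reduces_to_base(self, rng):
        X, y = _blobs(rng, 80)
        lone = [("lr", LogisticRegression(max_iter=200))]
        model = fit_stacking(X, y, folds=4, base_learners=lone,
                             meta_learner="identity")
        pred, _ = predict_stacking(model, X)
        direct = LogisticRegression(max_iter=200).fit(X, y).predict(X)
        np.testing.assert_array_equal(pred, direct)

    def test_empty_input_empty_output(self, rng):
        X, y = _blobs(rng, 40)
        model = fit_stacking(X, y, folds=4, base_learners=FAST_BASES)
        pred, score = predict_stacking(model, np.empty((0, 4)))
        assert len(pred) == 0 and len(score) == 0

    def test_width_mismatch_rejected(self, rng):
        X, y = _blobs(rng, 40)
        model = fit_stacking(X, y, folds=4, base_learners=FAST_BASES)
        with pytest.raises(ValueError, match="columns"):
            predict_stacking(model, np.zeros((2, 7)))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_stacking(rng.normal(size=(20, 3)), np.ones(20, int))


class TestCrossvalidate:
    def test_stratification_contract(self, rng):
        X = rng.normal(size=(100, 5))
        y = np.array([1] * 40 + [0] * 60)
        res = crossvalidate(X, y, folds=10, smote=None,
                            base_learners=FAST_BASES, stacking_folds=2)
        for fold in range(10):
            yf = y[res["fold_assignments"] == fold]
            assert abs((yf == 1).sum() - 4) <= 1
            assert abs((yf == 0).sum() - 6) <= 1

    def test_fold_assignments_reproducible(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array([0, 1] * 30)
        a = crossvalidate(X, y, folds=5, seed=42, smote=None,
                          base_learners=FAST_BASES, stacking_folds=2)
        b = crossvalidate(X, y, folds=5, seed=42, smote=None,
                          base_learners=FAST_BASES, stacking_folds=2)
        np.testing.assert_array_equal(a["fold_assignments"],
                                      b["fold_assignments"])
        np.testing.assert_array_equal(a["oof_predictions"], b["oof_predictions"])

    def test_fold_smote_leaves_test_rows_untouched(self, rng):
        """Evaluation covers exactly the original rows: SMOTE only inflates
        the training side of each fold."""
        X, y = _blobs(rng, 60)
        y[:45] = 0
        y[45:] = 1
        res = crossvalidate(X, y, folds=5, smote=SMOTEConfig(),
                            base_learners=FAST_BASES, stacking_folds=2)
        assert len(res["fold_assignments"]) == 60
        assert (res["fold_assignments"] >= 0).all()
        total = sum(m.tp + m.tn + m.fp + m.fn for m in res["fold_metrics"])
        assert total == 60

    def test_global_smote_scope_adds_synthetic_rows(self, rng):
        X, y = _blobs(rng, 60)
        y[:45] = 0
        y[45:] = 1
        res = crossvalidate(X, y, folds=5, smote=SMOTEConfig(),
                            smote_scope="global", base_learners=FAST_BASES,
                            stacking_folds=2)
        assert len(res["fold_assignments"]) == 90  # balanced 45/45

    def test_grouped_cv_keeps_groups_whole(self, rng):
        X, y = _blobs(rng, 60)
        groups = np.repeat(np.arange(10), 6)
        res = crossvalidate(X, y, folds=5, smote=None, groups=groups,
                            base_learners=FAST_BASES, stacking_folds=2)
        for g in range(10):
            folds = res["fold_assignments"][groups == g]
            assert len(set(folds.tolist())) == 1
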