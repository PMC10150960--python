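"""Fold planning, class weights, metrics oracles, PCA hygiene, SFFS behavior
on constructed instances, and the subject-leakage guarantee."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import matthews_corrcoef, precision_score, recall_score

from hypocause.classify import (
    ClassifierSpec,
    SFFSConfig,
    grouped_kfold,
    pca_transform,
    run_cv_experiment,
    sffs_select,
)
from hypocause.metrics import class_weights, confusion_counts, evaluate_metrics, mcc
from hypocause.nn import NeuralClassifier, NNConfig

# ---------------------------------------------------------------------------
# fold planning
# ---------------------------------------------------------------------------


class TestGroupedKfold:
    def _subject_vector(self, n_subjects=54, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.integers(5, 25, n_subjects)
        return np.repeat([f"S{i:02d}" for i in range(n_subjects)], counts)

    def test_validation_sets_partition_subjects(self):
        subjects = self._subject_vector()
        plan = grouped_kfold(subjects, k=10, seed=1)
        seen = [s for _, val in plan.outer for s in val]
        assert sorted(seen) == sorted(set(subjects))

    def test_train_validation_disjoint_everywhere(self):
        subjects = self._subject_vector()
        plan = grouped_kfold(subjects, k=10, seed=2)
        for (train, val), inner in zip(plan.outer, plan.inner):
            assert not train & val
            for itrain, ival in inner:
                assert not itrain & ival
                assert itrain | ival == train  # nested folds stay inside train

    def test_deterministic_given_seed(self):
        subjects = self._subject_vector()
        assert grouped_kfold(subjects, 10, seed=3) == grouped_kfold(subjects, 10, seed=3)
        assert grouped_kfold(subjects, 10, seed=3) != grouped_kfold(subjects, 10, seed=4)

    def test_balanced_episode_counts(self):
        subjects = self._subject_vector()
        plan = grouped_kfold(subjects, k=10, seed=5)
        sizes = [np.isin(subjects, list(val)).sum() for _, val in plan.outer]
        assert max(sizes) - min(sizes) <= 25  # within one large subject

    def test_k_exceeding_subjects_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            grouped_kfold(np.array(["a", "b"]), k=3, seed=0)


# ---------------------------------------------------------------------------
# class weights & metrics
# ---------------------------------------------------------------------------


class TestClassWeights:
    def test_balanced_classes_weight_one(self):
        labels = np.repeat([0, 1, 2], 30)
        assert class_weights(labels) == {0: 1.0, 1: 1.0, 2: 1.0}

    def test_binary_counts_hand_values(self):
        labels = np.array([0] * 60 + [1] * 30)
        w = class_weights(labels)
        assert w[0] == pytest.approx(0.75)
        assert w[1] == pytest.approx(1.5)

    def test_weights_sum_to_n_obs(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["a", "b", "c"], size=500, p=[0.6, 0.3, 0.1])
        w = class_weights(labels)
        assert sum(w[c] for c in labels) == pytest.approx(len(labels), abs=1e-9)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1, 0, 2])
        m = evaluate_metrics(y, y, classes=[0, 1, 2])
        for c in (0, 1, 2):
            assert m["per_class"][c] == {
                "precision": 1.0, "recall": 1.0, "f1": 1.0, "mcc": 1.0
            }

    def test_hand_confusion_values(self):
        # TP=45, FP=15, FN=5, TN=35
        y_true = np.array([1] * 50 + [0] * 50)
        y_pred = np.concatenate([np.ones(45), np.zeros(5), np.ones(15), np.zeros(35)])
        m = evaluate_metrics(y_true, y_pred, classes=[1])["per_class"][1]
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.9)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.9 / 1.65)
        expected_mcc = (45 * 35 - 15 * 5) / np.sqrt(60 * 50 * 50 * 40)
        assert m["mcc"] == pytest.approx(expected_mcc)

    def test_constant_predictor_mcc_zero(self):
        y_true = np.array([0, 1, 0, 1])
        y_pred = np.ones(4)
        m = evaluate_metrics(y_true, y_pred, classes=[1])["per_class"][1]
        assert m["mcc"] == 0.0
        assert m["precision"] == 0.5 and m["recall"] == 1.0

    def test_agrees_with_sklearn_on_random_vectors(self):
        """Independent cross-check of all four metrics on 200 random
        binary and 3-class label pairs."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = rng.choice([2, 3])
            n = int(rng.integers(5, 60))
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            m = evaluate_metrics(y_true, y_pred, classes=list(range(k)))
            for c in range(k):
                p_sk = precision_score(y_true == c, y_pred == c, zero_division=0)
                r_sk = recall_score(y_true == c, y_pred == c, zero_division=0)
                assert m["per_class"][c]["precision"] == pytest.approx(p_sk, abs=1e-12)
                assert m["per_class"][c]["recall"] == pytest.approx(r_sk, abs=1e-12)
                sk_mcc = matthews_corrcoef(y_true == c, y_pred == c)
                assert m["per_class"][c]["mcc"] == pytest.approx(sk_mcc, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.array([0, 1]), np.array([0]), 1)


# ---------------------------------------------------------------------------
# PCA hygiene
# ---------------------------------------------------------------------------


class TestPca:
    def test_variance_conserved_and_orthogonal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 6)) @ rng.normal(size=(6, 6))
        components, transform = pca_transform(X)
        Z = transform(X)
        # total variance of scores equals total variance of standardized input
        assert Z.var(axis=0, ddof=1).sum() == pytest.approx(6.0, rel=0.02)
        gram = (Z - Z.mean(0)).T @ (Z - Z.mean(0))
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.allclose(components @ components.T, np.eye(len(components)), atol=1e-10)

    def test_duplicated_column_gives_zero_variance_component(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 3))
        X = np.column_stack([x, x[:, 0]])
        _, transform = pca_transform(X)
        Z = transform(X)
        assert Z.var(axis=0).min() < 1e-20

    def test_transform_uses_training_statistics_only(self):
        rng = np.random.default_rng(2)
        X_train = rng.normal(size=(100, 4))
        _, transform = pca_transform(X_train)
        X_new = rng.normal(loc=5.0, size=(50, 4))  # shifted distribution
        Z_new = transform(X_new)
        # training stats applied unchanged: the shift survives into scores
        assert np.abs(Z_new.mean(0)).max() > 1.0


# ---------------------------------------------------------------------------
# SFFS constructed instances
# ---------------------------------------------------------------------------


def _inner_plan(groups, seed):
    return grouped_kfold(groups, 5, seed).outer


class TestSffs:
    CFG = SFFSConfig(n_trees=15, max_features=6, min_samples_leaf=10)

    def test_perfect_feature_found_first(self):
        rng = np.random.default_rng(0)
        n = 400
        g = rng.integers(0, 20, n)
        X = rng.normal(size=(n, 21))
        y = (X[:, 7] > 0).astype(int)  # feature 7 separates perfectly
        sel = sffs_select(X, y, g, _inner_plan(g, 0), seed=0, config=self.CFG)
        assert sel[0] == 7

    def test_returns_nonempty_on_pure_noise(self):
        rng = np.random.default_rng(1)
        n = 300
        g = rng.integers(0, 20, n)
        X = rng.normal(size=(n, 10))
        y = rng.integers(0, 2, n)
        sel = sffs_select(X, y, g, _inner_plan(g, 1), seed=1, config=self.CFG)
        assert len(sel) >= 1

    def test_floating_removes_redundant_feature(self):
        """f0 = f1 + f2 + noise is the best single feature, but once f1 and
        f2 are both in, f0 is redundant and the floating step drops it."""
        removed = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 600
            g = rng.integers(0, 30, n)
            f1, f2 = rng.normal(size=(2, n))
            f0 = f1 + f2 + rng.normal(0, 1.2, n)
            noise = rng.normal(size=(n, 3))
            X = np.column_stack([f0, f1, f2, noise])
            y = (f1 + f2 > 0).astype(int)
            sel = sffs_select(X, y, g, _inner_plan(g, seed), seed=seed, config=self.CFG)
            if {1, 2} <= set(sel) and 0 not in sel:
                removed += 1
        assert removed >= 3


# ---------------------------------------------------------------------------
# experiment-level leakage
# ---------------------------------------------------------------------------


class TestLeakage:
    def test_poisoning_validation_subject_leaves_model_unchanged(self, default_features):
        """Corrupting every feature of one validation subject must not change
        the predictions for the other validation subjects of that fold."""
        from tests.conftest import CORE_FEATURES

        feats = default_features[["episode_id", "subject_id", "category"] + CORE_FEATURES[:12]]
        spec = ClassifierSpec(
            scenario="ovr:ACTIVITY",
            k_outer=6,
            seed=3,
            sffs=SFFSConfig(n_trees=8, max_features=3, min_samples_leaf=20, patience=0),
            nn=NNConfig(max_epochs=60, patience=60),
        )
        plan = grouped_kfold(feats["subject_id"].to_numpy(), spec.k_outer, spec.seed)
        victim = sorted(plan.outer[0][1])[0]  # a validation subject of fold 0

        poisoned = feats.copy()
        mask = poisoned["subject_id"] == victim
        poisoned.loc[mask, CORE_FEATURES[:12]] = 999.0

        rep_a = run_cv_experiment(feats, spec, folds=[0])
        rep_b = run_cv_experiment(poisoned, spec, folds=[0])
        # the victim is validation-only in fold 0: feature selection and the
        # trained model must be identical, so every non-victim validation
        # episode gets the same prediction
        assert rep_a.selected_features == rep_b.selected_features
        victim_eids = set(feats.loc[mask, "episode_id"])
        pa = rep_a.predictions[~rep_a.predictions["episode_id"].isin(victim_eids)]
        pb = rep_b.predictions[~rep_b.predictions["episode_id"].isin(victim_eids)]
        pd.testing.assert_frame_equal(
            pa.reset_index(drop=True), pb.reset_index(drop=True)
        )
        assert len(pa) > 0
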