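"""Augmentation, SVM training, sector scoring, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from vepkit.classify import (
    Model,
    augment_dataset,
    evaluate,
    load_model,
    save_model,
    score_sectors,
    train_classifier,
    DEFAULT_AUGMENT_TARGET,
)
from vepkit.features import ReferenceTemplate


def _blobs(n=60, d=5, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, d))
    b = rng.normal(size=(n, d)) + sep
    X = np.vstack([a, b])
    y = np.array(["normal"] * n + ["abnormal"] * n)
    return X, y


class TestAugmentation:
    def test_default_target_is_65536(self):
        assert DEFAULT_AUGMENT_TARGET == 65536

    def test_requested_count_produced(self):
        X, y = _blobs(20)
        aug = augment_dataset(X, y, target_count=500, seed=1)
        assert len(aug.samples) == 500 and len(aug.labels) == 500

    def test_samples_lie_on_source_neighbor_segment(self):
        """Geometry oracle: |src-aug| + |aug-nn| == |src-nn| within 1e-9."""
        X, y = _blobs(30, seed=3)
        aug = augment_dataset(X, y, target_count=300, seed=2)
        s = X[aug.source_index]
        nbr = X[aug.neighbor_index]
        d_total = np.linalg.norm(s - nbr, axis=1)
        d_sum = np.linalg.norm(s - aug.samples, axis=1) + np.linalg.norm(
            aug.samples - nbr, axis=1
        )
        assert np.all(np.abs(d_sum - d_total) < 1e-9)

    def test_neighbors_are_same_class_and_not_self(self):
        X, y = _blobs(25, seed=4)
        aug = augment_dataset(X, y, target_count=200, seed=5)
        assert np.all(y[aug.source_index] == y[aug.neighbor_index])
        assert np.all(aug.source_index != aug.neighbor_index)

    def test_mixing_factors_clipped_to_unit_interval(self):
        X, y = _blobs(25)
        aug = augment_dataset(X, y, target_count=2000, seed=6)
        assert aug.mixing_factor.min() >= 0.0 and aug.mixing_factor.max() <= 1.0

    def test_class_proportions_preserved(self):
        X, y = _blobs(40)
        frac = (y == "abnormal").mean()
        aug = augment_dataset(X, y, target_count=20000, seed=7)
        assert abs((aug.labels == "abnormal").mean() - frac) < 0.02

    @given(seed=hst.integers(0, 2**20), target=hst.integers(1, 200))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_augmented_samples_always_convex_mixtures(self, seed, target):
        """For any seed and target, every emitted sample is a convex
        combination of its source and a same-class neighbor."""
        X, y = _blobs(15, d=3, seed=1)
        aug = augment_dataset(X, y, target_count=target, seed=seed)
        assert len(aug.samples) == target
        s, nbr = X[aug.source_index], X[aug.neighbor_index]
        d_sum = np.linalg.norm(s - aug.samples, axis=1) + np.linalg.norm(
            aug.samples - nbr, axis=1
        )
        assert np.all(np.abs(d_sum - np.linalg.norm(s - nbr, axis=1)) < 1e-9)
        assert np.all(y[aug.source_index] == aug.labels)

    def test_class_with_single_member_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.array(["normal"] * 4 + ["abnormal"])
        with pytest.raises(ValueError, match="fewer than 2"):
            augment_dataset(X, y, target_count=10)


class TestTraining:
    def test_separable_blobs_high_training_accuracy(self):
        X, y = _blobs(60)
        model = train_classifier(X, y, reference=ReferenceTemplate(np.zeros(200)))
        pred = model.pipeline.predict(X)
        assert (pred == y).mean() >= 0.99

    def test_label_swap_mirrors_probabilities(self):
        X, y = _blobs(60, seed=9)
        ref = ReferenceTemplate(np.zeros(200))
        m1 = train_classifier(X, y, reference=ref, seed=0)
        swapped = np.where(y == "normal", "abnormal", "normal")
        m2 = train_classifier(X, swapped, reference=ref, seed=0)
        p1 = m1.pipeline.predict_proba(X)[:, m1.normal_column]
        p2 = m2.pipeline.predict_proba(X)[:, m2.normal_column]
        assert np.allclose(p1, 1.0 - p2, atol=0.05)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, np.array(["normal"] * 20))

    def test_deterministic_for_fixed_seed(self):
        X, y = _blobs(40, seed=2)
        ref = ReferenceTemplate(np.zeros(200))
        p1 = train_classifier(X, y, reference=ref, seed=3).pipeline.predict_proba(X)
        p2 = train_classifier(X, y, reference=ref, seed=3).pipeline.predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_save_load_round_trip(self, tmp_path):
        X, y = _blobs(40)
        ref = ReferenceTemplate(np.linspace(0, 1, 200), "test")
        model = train_classifier(X, y, reference=ref, seed=1)
        p = tmp_path / "model.joblib"
        save_model(model, p)
        back = load_model(p)
        assert np.array_equal(
            back.pipeline.predict_proba(X), model.pipeline.predict_proba(X)
        )
        assert np.array_equal(back.reference.waveform, ref.waveform)
        assert back.hyperparams == model.hyperparams


class _StubPipeline:
    """Deterministic probability source for scoring-logic tests."""

    classes_ = np.array(["abnormal", "normal"])

    def __init__(self, p_normal):
        self.p = np.asarray(p_normal, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.p, self.p])

    def predict(self, X):
        return np.where(self.p >= 0.5, "normal", "abnormal")


def _stub_model(p_normal, n_features=19):
    from vepkit.features import FEATURE_NAMES

    return Model(
        pipeline=_StubPipeline(p_normal),
        reference=ReferenceTemplate(np.zeros(200)),
        feature_names=FEATURE_NAMES[:n_features],
    )


class TestScoring:
    def test_half_probability_scores_50_and_calls_normal(self):
        scores = score_sectors(_stub_model([0.5]), np.zeros((1, 19)))
        assert scores[0].score == 50.0 and scores[0].call == "normal"

    def test_certain_normal_scores_100(self):
        scores = score_sectors(_stub_model([1.0]), np.zeros((1, 19)))
        assert scores[0].score == 100.0 and scores[0].gray_level == 1.0

    def test_score_order_matches_probability_order(self):
        p = np.array([0.9, 0.1, 0.4, 0.7, 0.55])
        scores = score_sectors(_stub_model(p), np.zeros((5, 19)))
        vals = [s.score for s in scores]
        assert np.array_equal(np.argsort(vals), np.argsort(p))

    def test_call_and_ambiguous_bands(self):
        p = np.array([0.3, 0.45, 0.49, 0.62])
        s = score_sectors(_stub_model(p), np.zeros((4, 19)))
        assert [x.call for x in s] == ["abnormal", "abnormal", "abnormal", "normal"]
        assert [x.ambiguous for x in s] == [False, True, True, False]

    def test_schema_mismatch_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            score_sectors(_stub_model([0.5]), np.zeros((1, 7)))


class TestEvaluation:
    def test_perfect_predictions_all_metrics_one(self):
        y = np.array(["abnormal"] * 10 + ["normal"] * 10)
        p = np.where(y == "normal", 0.9, 0.1)
        m = evaluate(_stub_model(p), np.zeros((20, 19)), y)
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == (1.0, 1.0, 1.0, 1.0)

    def test_confusion_matrix_arithmetic(self):
        # TP=9, FN=1 (abnormal), TN=8, FP=2 (normal)
        y = np.array(["abnormal"] * 10 + ["normal"] * 10)
        p = np.concatenate([np.full(9, 0.1), [0.9], np.full(8, 0.9), np.full(2, 0.1)])
        m = evaluate(_stub_model(p), np.zeros((20, 19)), y)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(17 / 20)

    def test_auc_equals_mann_whitney_brute_force(self):
        """Pairwise-comparison oracle on 50 scored samples."""
        rng = np.random.default_rng(12)
        y = np.array(["abnormal"] * 25 + ["normal"] * 25)
        p_normal = np.clip(rng.normal(np.where(y == "normal", 0.6, 0.4), 0.2), 0, 1)
        m = evaluate(_stub_model(p_normal), np.zeros((50, 19)), y)
        p_ab = 1 - p_normal
        ab, no = p_ab[y == "abnormal"], p_ab[y == "normal"]
        wins = sum((a > b) + 0.5 * (a == b) for a in ab for b in no)
        assert m.auc == pytest.approx(wins / (len(ab) * len(no)), abs=1e-12)

    def test_single_class_eval_flags_undefined_auc(self):
        y = np.array(["normal"] * 8)
        m = evaluate(_stub_model(np.full(8, 0.9)), np.zeros((8, 19)), y)
        assert not m.auc_defined and np.isnan(m.auc)
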