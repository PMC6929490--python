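"""Probability stacking: meta-features, meta-classifier, fused prediction."""

import time

import numpy as np
import pytest

from memtype.fusion import (build_meta_features, load_meta, normalize_scores,
                            predict_fused, save_meta, train_meta,
                            train_meta_kfold)


def simulate_base_probs(labels, known, sharpness, rng, k=4):
    """Base-model output that is confident on ``known`` classes only.

    On its known classes the model concentrates mass on the truth; on the
    others it spreads mass over the complementary subset (pure confusion).
    """
    n = len(labels)
    logits = rng.normal(0.0, 0.1, size=(n, k))
    for i, lab in enumerate(labels):
        if lab in known:
            logits[i, lab - 1] += sharpness
        else:
            unknown = [c for c in range(1, k + 1) if c not in known]
            logits[i, [c - 1 for c in unknown]] += sharpness / 2
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class TestMetaFeatures:
    def test_width_sixteen_sequence_half_first(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.random((5, 8)), rng.random((5, 8))
        feats = build_meta_features(p1, p2)
        assert feats.shape == (5, 16)
        np.testing.assert_array_equal(feats[:, :8], p1)

    def test_self_concatenation_gives_identical_halves(self):
        p = np.random.default_rng(1).random((3, 8))
        feats = build_meta_features(p, p)
        np.testing.assert_array_equal(feats[:, :8], feats[:, 8:])

    def test_index_mapping_against_loop_oracle(self):
        rng = np.random.default_rng(2)
        p1, p2 = rng.random((4, 8)), rng.random((4, 8))
        feats = build_meta_features(p1, p2)
        for n in range(4):
            for j in range(8):
                assert feats[n, 8 + j] == p2[n, j]
                assert feats[n, j] == p1[n, j]

    def test_row_count_mismatch(self):
        with pytest.raises(ValueError):
            build_meta_features(np.zeros((2, 8)), np.zeros((3, 8)))

    def test_normalize_scores_sums_to_one(self):
        raw = np.random.default_rng(3).random((6, 8)) * 0.9
        np.testing.assert_allclose(normalize_scores(raw).sum(axis=1), 1.0)


class TestTrainMeta:
    def test_perfect_features_keep_perfect_accuracy(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(1, 5, 200)
        p_seq = np.eye(4)[labels - 1] * 0.94 + 0.015   # one-hot-perfect
        p_evo = np.full((200, 4), 0.25)
        meta = train_meta(build_meta_features(p_seq, p_evo), labels)
        _, pred = predict_fused(meta, p_seq, p_evo)
        assert np.mean(pred == labels) >= np.mean(p_seq.argmax(1) + 1 == labels)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 5, 120)
        feats = rng.random((120, 16))
        meta1 = train_meta(feats, labels)
        perm = rng.permutation(120)
        meta2 = train_meta(feats[perm], labels[perm])
        np.testing.assert_allclose(meta1.coef, meta2.coef, atol=1e-6)

    def test_degenerate_identical_features_predict_majority(self):
        labels = np.array([1] * 70 + [2] * 30)
        feats = np.ones((100, 16)) * 0.5
        meta = train_meta(feats, labels)
        _, pred = predict_fused(meta, feats[:, :8], feats[:, 8:])
        assert (pred == 1).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_meta(np.random.random((10, 16)), np.ones(10, dtype=int))


class TestPredictFused:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(1, 5, 100)
        p1 = simulate_base_probs(labels, {1, 2}, 6.0, rng)
        p2 = simulate_base_probs(labels, {3, 4}, 6.0, rng)
        meta = train_meta(build_meta_features(p1, p2), labels)
        probs, _ = predict_fused(meta, p1, p2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_agreeing_confident_bases_win(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(1, 5, 200)
        p1 = simulate_base_probs(labels, {1, 2, 3, 4}, 8.0, rng)
        p2 = simulate_base_probs(labels, {1, 2, 3, 4}, 8.0, rng)
        meta = train_meta(build_meta_features(p1, p2), labels)
        _, pred = predict_fused(meta, p1, p2)
        assert np.mean(pred == labels) > 0.99

    def test_empty_input_gives_empty_output(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(1, 5, 50)
        p1 = simulate_base_probs(labels, {1, 2}, 6.0, rng)
        p2 = simulate_base_probs(labels, {3, 4}, 6.0, rng)
        meta = train_meta(build_meta_features(p1, p2), labels)
        probs, pred = predict_fused(meta, p1[:0], p2[:0])
        assert probs.shape[0] == 0 and pred.shape[0] == 0

    def test_untrained_meta_rejected(self):
        with pytest.raises(ValueError, match="trained"):
            predict_fused(None, np.zeros((1, 8)), np.zeros((1, 8)))


class TestComplementaryStrengths:
    def test_fusion_beats_both_bases(self):
        # each base perfectly separates a disjoint half of the classes;
        # stacking must combine them without losing the stronger base
        rng = np.random.default_rng(9)
        y_meta = rng.integers(1, 5, 400)
        y_test = rng.integers(1, 5, 400)
        p1_meta = simulate_base_probs(y_meta, {1, 2}, 8.0, rng)
        p2_meta = simulate_base_probs(y_meta, {3, 4}, 8.0, rng)
        p1_test = simulate_base_probs(y_test, {1, 2}, 8.0, rng)
        p2_test = simulate_base_probs(y_test, {3, 4}, 8.0, rng)
        meta = train_meta(build_meta_features(p1_meta, p2_meta), y_meta)
        _, fused = predict_fused(meta, p1_test, p2_test)
        base1 = np.mean(p1_test.argmax(1) + 1 == y_test)
        base2 = np.mean(p2_test.argmax(1) + 1 == y_test)
        fused_osr = np.mean(fused == y_test)
        assert fused_osr >= max(base1, base2) - 0.02
        assert fused_osr > 0.95  # complementary information is combined

    def test_kfold_stacking_mode(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(1, 5, 200)
        p1 = simulate_base_probs(labels, {1, 2}, 8.0, rng)
        p2 = simulate_base_probs(labels, {3, 4}, 8.0, rng)
        meta = train_meta_kfold(lambda tr, te: p1[te], lambda tr, te: p2[te],
                                None, None, labels, n_folds=4)
        _, pred = predict_fused(meta, p1, p2)
        assert np.mean(pred == labels) > 0.9


class TestLatency:
    def test_meta_step_is_orders_of_magnitude_cheaper_than_bases(
            self, seq_data, pssm_data):
        from memtype.capsule_model import (EvoModelSpec,
                                           build_evolutionary_model,
                                           predict_proba_caps)
        from memtype.sequence_model import (SequenceModelSpec,
                                            build_sequence_model,
                                            predict_proba_seq)
        x_seq, y, _ = seq_data
        x_evo, _, _ = pssm_data
        seq = build_sequence_model(SequenceModelSpec().scaled_down(seed=0))
        evo = build_evolutionary_model(EvoModelSpec().scaled_down(seed=0))
        idx = np.random.default_rng(12).choice(len(y), 100, replace=False)
        t0 = time.perf_counter()
        p1 = predict_proba_seq(seq, x_seq[idx])
        p2 = normalize_scores(predict_proba_caps(evo, x_evo[idx]))
        base_time = time.perf_counter() - t0
        meta = train_meta(build_meta_features(p1, p2), y[idx])
        meta_time = min(
            _timed(lambda: predict_fused(meta, p1, p2)) for _ in range(5))
        assert meta_time < 0.01 * base_time


def _timed(fn):
    t0 = time.perf_counter()
    fn()
    return time.perf_counter() - t0


class TestPersistence:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        labels = rng.integers(1, 5, 100)
        feats = rng.random((100, 16))
        meta = train_meta(feats, labels)
        path = tmp_path / "meta.json"
        save_meta(path, meta)
        back = load_meta(path)
        np.testing.assert_array_equal(back.coef, meta.coef)
        np.testing.assert_array_equal(back.classes, meta.classes)

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "other"}')
        with pytest.raises(ValueError, match="format"):
            load_meta(path)
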