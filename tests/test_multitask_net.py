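"""Multi-task discriminator: encoder contracts, hard parameter sharing,
trainability on separable fixtures, evaluation metrics."""

import numpy as np
import pytest

from temporient import multitask_net as mt
from temporient import nn
from temporient import synthetic_data as sd
from temporient.corpus_io import Tweet
from temporient.weak_labelers import build_vocab


SMALL = dict(embedding_dim=16, recurrent_units=8, conv_filters=8,
             shared_mlp_units=16, task_dense_units=8)


@pytest.fixture(scope="module")
def fixture_data():
    return sd.separable_fixture(n_per_task=60, seed=3)


@pytest.fixture(scope="module")
def trained_model(fixture_data):
    temporal, emotion = fixture_data
    cfg = mt.ModelConfig(embedding_dim=24, recurrent_units=16, conv_filters=16,
                         shared_mlp_units=32, task_dense_units=16,
                         epochs=60, seed=0)
    return mt.train_multitask(temporal, emotion, cfg)


class TestWordVectors:
    def test_in_vocab_rows_copied(self, tmp_path):
        p = tmp_path / "vec.txt"
        p.write_text("\n".join(f"tok{i} " + " ".join(["%d" % i] * 4)
                               for i in range(5)) + "\n")
        vocab = {"<pad>": 0, "tok1": 1, "tok3": 2, "unseen": 3}
        table = mt.load_word_vectors(p, vocab, dim=4, seed=0)
        np.testing.assert_allclose(table[1], [1, 1, 1, 1])
        np.testing.assert_allclose(table[2], [3, 3, 3, 3])
        assert np.abs(table[3]).max() < 1.0  # noise row, small variance
        np.testing.assert_allclose(table[0], 0.0)  # pad row stays zero

    def test_reproducible_random_table_without_file(self):
        vocab = {f"t{i}": i for i in range(50)}
        a = mt.load_word_vectors(None, vocab, dim=20, seed=4)
        b = mt.load_word_vectors(None, vocab, dim=20, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_dimension_mismatch_rejected(self, tmp_path):
        p = tmp_path / "vec.txt"
        p.write_text("a 1 2 3\n")
        with pytest.raises(ValueError, match="dimension"):
            mt.load_word_vectors(p, {"a": 0}, dim=5)


class TestEncoder:
    def _model(self):
        vocab = build_vocab([["a", "b", "c", "d"]])
        cfg = mt.ModelConfig(**SMALL, seed=0)
        return mt.MultiTaskModel(cfg, vocab)

    def test_output_shape(self):
        model = self._model()
        out = model.encode([["a", "b"], ["c", "d", "a"]])
        assert out.data.shape == (2, 16)

    def test_eval_mode_deterministic_and_permutation_equivariant(self):
        model = self._model()
        batch = [["a", "b", "c"], ["d", "a"], ["b"]]
        out1 = model.encode(batch).data
        out2 = model.encode(batch).data
        np.testing.assert_array_equal(out1, out2)
        perm = model.encode([batch[2], batch[0], batch[1]]).data
        np.testing.assert_allclose(perm, out1[[2, 0, 1]], atol=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            self._model().encode([])


class TestHardParameterSharing:
    def test_gradients_from_either_task_reach_shared_encoder(self, fixture_data):
        temporal, emotion = fixture_data
        vocab = build_vocab([r.tweet.tokens for r in temporal + emotion])
        cfg = mt.ModelConfig(**SMALL, seed=1)
        for task in ("temporal", "emotion"):
            model = mt.MultiTaskModel(cfg, vocab)
            before = [p.data.copy() for p in model.shared_params()]
            opt = nn.RMSProp(model.all_params(), lr=0.01)
            shared = model.encode([r.tweet.tokens for r in temporal[:8]], train=True)
            if task == "temporal":
                loss = nn.softmax_cross_entropy(model.temporal_logits(shared),
                                                np.zeros(8, dtype=int))
            else:
                logits, intensity = model.emotion_outputs(shared)
                loss = nn.add(nn.softmax_cross_entropy(logits, np.zeros(8, dtype=int)),
                              nn.mean_squared_error(intensity, np.full((8, 1), 0.5)))
            loss.backward()
            opt.step()
            changed = [not np.array_equal(b, p.data)
                       for b, p in zip(before, model.shared_params())]
            assert all(changed), f"{task} step left some shared parameters untouched"

    def test_single_task_ablation_has_no_emotion_updates(self, fixture_data):
        temporal, _ = fixture_data
        cfg = mt.ModelConfig(**SMALL, epochs=2, seed=0)
        model = mt.train_multitask(temporal, None, cfg)
        assert model.single_task
        preds = model.predict([r.tweet for r in temporal[:4]])
        assert preds.temporal_probs.shape == (4, 3)


class TestTraining:
    def test_overfits_separable_fixture(self, trained_model, fixture_data):
        temporal, emotion = fixture_data
        preds_t = trained_model.predict([r.tweet for r in temporal])
        codes = {"past": 1, "present": 2, "future": 3}
        acc_t = np.mean(preds_t.temporal_hard ==
                        [codes[r.temporal_class] for r in temporal])
        preds_e = trained_model.predict([r.tweet for r in emotion])
        eidx = {e: i for i, e in enumerate(("joy", "sadness", "anger", "fear"))}
        acc_e = np.mean(preds_e.emotion_hard ==
                        [eidx[r.emotion_class] for r in emotion])
        assert acc_t >= 0.95 and acc_e >= 0.95

    def test_loss_decreases(self, trained_model):
        trace = trained_model.loss_trace
        assert trace[-1] < trace[0]

    def test_same_seed_identical_weights(self, fixture_data):
        temporal, emotion = fixture_data
        cfg = mt.ModelConfig(**SMALL, epochs=3, seed=11)
        m1 = mt.train_multitask(temporal, emotion, cfg)
        m2 = mt.train_multitask(temporal, emotion, cfg)
        for a, b in zip(m1.all_params(), m2.all_params()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_empty_temporal_data_rejected(self):
        with pytest.raises(ValueError):
            mt.train_multitask([], None, mt.ModelConfig(**SMALL))


class TestPredictions:
    def test_probability_rows_sum_to_one_and_intensity_in_range(self, trained_model):
        tweets = [Tweet(id=f"x{i}", text="yesterday happy thing") for i in range(5)]
        preds = trained_model.predict(tweets)
        np.testing.assert_allclose(preds.temporal_probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(preds.emotion_probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((preds.intensity >= 0) & (preds.intensity <= 1))

    def test_checkpoint_roundtrip(self, trained_model, fixture_data, tmp_path):
        temporal, _ = fixture_data
        path = tmp_path / "model.ckpt"
        trained_model.save(path)
        back = mt.MultiTaskModel.load(path)
        tweets = [r.tweet for r in temporal[:6]]
        np.testing.assert_array_equal(back.predict(tweets).temporal_probs,
                                      trained_model.predict(tweets).temporal_probs)


class TestEvaluate:
    def _perfect_predictions(self):
        ids = [f"t{i}" for i in range(6)]
        temporal = np.eye(3)[[0, 1, 2, 0, 1, 2]]
        emotion = np.eye(4)[[0, 1, 2, 3, 0, 1]]
        intensity = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 0.2])
        return mt.Predictions(ids, temporal, emotion, intensity)

    def test_perfect_predictions_score_one(self):
        preds = self._perfect_predictions()
        gold_t = ["past", "present", "future"] * 2
        gold_e = ["joy", "sadness", "anger", "fear", "joy", "sadness"]
        out = mt.evaluate(preds, gold_t, gold_e, preds.intensity)
        assert out["temporal"]["accuracy"] == 1.0
        assert all(v["f1"] == 1.0 for v in out["temporal"]["per_class"].values())
        assert out["intensity_pearson_r"] == pytest.approx(1.0)

    def test_inverted_intensity_gives_minus_one(self):
        preds = self._perfect_predictions()
        out = mt.evaluate(preds, gold_intensity=1.0 - preds.intensity)
        assert out["intensity_pearson_r"] == pytest.approx(-1.0)

    def test_constant_gold_intensity_flagged_undefined(self):
        preds = self._perfect_predictions()
        out = mt.evaluate(preds, gold_intensity=np.full(6, 0.5))
        assert out["intensity_pearson_r"] is None

    def test_confusion_matches_hand_count(self):
        # 6 items: gold past,past,present,present,future,future
        # predicted past,present,present,present,future,past
        temporal = np.eye(3)[[0, 1, 1, 1, 2, 0]]
        preds = mt.Predictions([f"t{i}" for i in range(6)], temporal,
                               np.full((6, 4), 0.25), np.zeros(6))
        gold = ["past", "past", "present", "present", "future", "future"]
        rep = mt.evaluate(preds, gold_temporal=gold)["temporal"]
        assert rep["confusion"] == [[1, 1, 0], [0, 2, 0], [1, 0, 1]]
        assert rep["per_class"]["past"]["precision"] == pytest.approx(0.5)
        assert rep["per_class"]["past"]["recall"] == pytest.approx(0.5)
        assert rep["per_class"]["present"]["recall"] == pytest.approx(1.0)
        assert rep["accuracy"] == pytest.approx(4 / 6)
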