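"""Generative label model: exactness against brute-force enumeration,
recovery on simulated labelers, structure estimation, balanced selection."""

import numpy as np
import pytest

from _oracles import brute_force_nll, brute_force_posterior, random_instance
from temporient import label_model as lm
from temporient import synthetic_data as sd
from temporient.corpus_io import Tweet
from temporient.weak_labelers import LabelMatrix


class TestFactorFeatures:
    def test_accuracy_propensity_correlation_indicators(self):
        S = lm.CorrelationSet([(0, 1)])
        f = lm.factor_features(np.array([1, 1]), 1, S)
        np.testing.assert_array_equal(f, [1, 1, 1, 1, 1])
        f = lm.factor_features(np.array([0, 2]), 1, lm.CorrelationSet())
        np.testing.assert_array_equal(f, [0, 0, 0, 1])

    def test_abstain_row_has_zero_acc_and_lab(self):
        for y in (1, 2, 3):
            f = lm.factor_features(np.array([0, 0, 0]), y, lm.CorrelationSet())
            np.testing.assert_array_equal(f[:6], np.zeros(6))


class TestExactness:
    def test_zero_weights_closed_form(self):
        for M, L in [(1, 2), (5, 3), (10, 1)]:
            mat = LabelMatrix(np.ones((M, L), dtype=int), [f"l{q}" for q in range(L)])
            w = lm.FactorWeights.zeros(L, lm.CorrelationSet())
            nll = lm.neg_log_marginal_likelihood(w, mat)
            assert nll == pytest.approx(M * L * np.log(4), abs=1e-10)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            matrix, structure, weights = random_instance(rng)
            fast = lm.neg_log_marginal_likelihood(weights, matrix, structure)
            slow = brute_force_nll(weights, matrix, structure)
            assert fast == pytest.approx(slow, abs=1e-8)
            post = lm.posterior_labels(weights, matrix, structure)
            np.testing.assert_allclose(
                post.probs, brute_force_posterior(weights, matrix, structure),
                atol=1e-10)

    def test_non_finite_weights_rejected(self):
        with pytest.raises(ValueError):
            lm.FactorWeights(np.array([np.inf]), np.array([0.0]))


class TestPosterior:
    def test_all_abstain_row_uniform(self):
        mat = LabelMatrix(np.array([[0, 0]]), ["a", "b"])
        w = lm.FactorWeights(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        post = lm.posterior_labels(w, mat)
        np.testing.assert_allclose(post.probs[0], [1 / 3] * 3, atol=1e-12)
        assert post.hard[0] == 1  # tie broken by class order

    def test_unanimous_row_with_positive_acc_weight(self):
        mat = LabelMatrix(np.array([[2, 2, 2]]), ["a", "b", "c"])
        w = lm.FactorWeights(np.ones(3), np.zeros(3))
        post = lm.posterior_labels(w, mat)
        assert post.hard[0] == 2

    def test_rows_sum_to_one(self, rng):
        matrix, structure, weights = random_instance(rng, max_m=5, max_l=4)
        post = lm.posterior_labels(weights, matrix, structure)
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)


class TestFitGenerative:
    def test_recovers_accuracy_ordering_and_beats_majority_vote(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(1, 4, size=1000)
        specs = [sd.LFSpec(a, 1.0) for a in (0.9, 0.7, 0.5)]
        mat = sd.simulate_lf_matrix(truth, specs, seed=6)
        weights = lm.fit_generative(mat)
        assert weights.acc[0] > weights.acc[1] > weights.acc[2]
        post = lm.posterior_labels(weights, mat)
        votes = np.stack([(mat.entries == y).sum(axis=1) for y in (1, 2, 3)], axis=1)
        majority = votes.argmax(axis=1) + 1
        post_acc = (post.hard == truth).mean()
        mv_acc = (majority == truth).mean()
        assert post_acc >= mv_acc - 0.01

    def test_single_perfect_lf_recovered_exactly(self, rng):
        truth = rng.integers(1, 4, size=200)
        mat = sd.simulate_lf_matrix(truth, [sd.LFSpec(1.0, 1.0)], seed=1)
        weights = lm.fit_generative(mat)
        post = lm.posterior_labels(weights, mat)
        np.testing.assert_array_equal(post.hard, mat.entries[:, 0])

    def test_nll_trace_non_increasing(self, rng):
        truth = rng.integers(1, 4, size=300)
        mat = sd.simulate_lf_matrix(truth, [sd.LFSpec(0.8, 0.9), sd.LFSpec(0.6, 0.9)],
                                    seed=2)
        weights = lm.fit_generative(mat, None, {"iterations": 150})
        trace = np.array(weights.nll_trace)
        assert trace[-1] <= trace[0]
        assert np.all(np.diff(trace) <= 1e-6)

    def test_all_abstain_matrix_rejected(self):
        mat = LabelMatrix(np.zeros((5, 2), dtype=int), ["a", "b"])
        with pytest.raises(ValueError):
            lm.fit_generative(mat)

    def test_column_permutation_symmetry(self, rng):
        truth = rng.integers(1, 4, size=400)
        specs = [sd.LFSpec(0.85, 0.9), sd.LFSpec(0.6, 0.8), sd.LFSpec(0.7, 1.0)]
        mat = sd.simulate_lf_matrix(truth, specs, seed=9)
        perm = [2, 0, 1]
        mat_p = LabelMatrix(mat.entries[:, perm], [mat.lf_names[i] for i in perm])
        w = lm.fit_generative(mat)
        w_p = lm.fit_generative(mat_p)
        np.testing.assert_allclose(w_p.acc, w.acc[perm], atol=1e-6)
        np.testing.assert_allclose(
            lm.posterior_labels(w_p, mat_p).probs,
            lm.posterior_labels(w, mat).probs, atol=1e-8)


class TestStructureEstimation:
    def test_planted_copy_pair_found_independent_excluded(self):
        truth = np.random.default_rng(3).integers(1, 4, size=2000)
        specs = [sd.LFSpec(0.8, 0.9),
                 sd.LFSpec(0.8, 0.9, copy_of=0, agreement=0.95),
                 sd.LFSpec(0.7, 0.9)]
        mat = sd.simulate_lf_matrix(truth, specs, seed=4)
        S = lm.estimate_structure(mat)
        assert (0, 1) in S.pairs
        assert (0, 2) not in S.pairs and (1, 2) not in S.pairs

    def test_single_lf_gives_empty_set(self, rng):
        truth = rng.integers(1, 4, size=100)
        mat = sd.simulate_lf_matrix(truth, [sd.LFSpec(0.9, 1.0)], seed=0)
        assert len(lm.estimate_structure(mat)) == 0

    def test_all_abstain_gives_empty_set(self):
        mat = LabelMatrix(np.zeros((50, 3), dtype=int), ["a", "b", "c"])
        assert len(lm.estimate_structure(mat)) == 0

    def test_too_few_rows_gives_empty_set(self, rng):
        mat = LabelMatrix(rng.integers(0, 4, (10, 2)), ["a", "b"])
        assert len(lm.estimate_structure(mat)) == 0


class TestBalancedSelection:
    def _posterior(self, probs):
        probs = np.asarray(probs, dtype=float)
        return lm.PosteriorLabels(probs, probs.argmax(axis=1) + 1)

    def _tweets(self, n):
        return [Tweet(id=f"t{i}", text=f"text {i}") for i in range(n)]

    def test_counts_and_remainder_rule(self, rng):
        probs = []
        for k in range(3):
            for _ in range(40):
                row = np.full(3, 0.1)
                row[k] = 0.8
                row += rng.uniform(0, 0.01, 3)
                probs.append(row / row.sum())
        post = self._posterior(probs)
        tweets = self._tweets(len(probs))
        records = lm.select_balanced_training(post, tweets, 90)
        counts = {c: 0 for c in ("past", "present", "future")}
        for r in records:
            counts[r.temporal_class] += 1
        assert counts == {"past": 30, "present": 30, "future": 30}
        records91 = lm.select_balanced_training(post, tweets, 91)
        counts91 = [sum(r.temporal_class == c for r in records91)
                    for c in ("past", "present", "future")]
        assert counts91 == [31, 30, 30]

    def test_sorted_by_descending_confidence_within_class(self, rng):
        probs = [[0.5 + 0.004 * i, 0.3 - 0.002 * i, 0.2 - 0.002 * i]
                 for i in range(30)]
        probs = probs + [[0.1, 0.8, 0.1]] * 30 + [[0.1, 0.1, 0.8]] * 30
        post = self._posterior(probs)
        records = lm.select_balanced_training(post, self._tweets(90), 30)
        past = [r for r in records if r.temporal_class == "past"]
        confs = [r.confidence for r in past]
        assert confs == sorted(confs, reverse=True)

    def test_insufficient_candidates_error_states_achievable(self):
        probs = [[0.8, 0.1, 0.1]] * 10 + [[0.1, 0.8, 0.1]] * 2 + [[0.1, 0.1, 0.8]] * 10
        post = self._posterior(probs)
        with pytest.raises(ValueError, match="achievable"):
            lm.select_balanced_training(post, self._tweets(22), 21)

    def test_uniform_rows_excluded(self):
        probs = [[1 / 3] * 3] * 5 + [[0.8, 0.1, 0.1]] * 2 \
            + [[0.1, 0.8, 0.1]] * 2 + [[0.1, 0.1, 0.8]] * 2
        post = self._posterior(probs)
        records = lm.select_balanced_training(post, self._tweets(11), 6)
        assert all(r.confidence > 0.34 for r in records)


class TestSerialization:
    def test_weights_json_roundtrip(self, tmp_path):
        S = lm.CorrelationSet([(0, 2)])
        w = lm.FactorWeights(np.array([0.1, 0.2, 0.3]), np.array([-0.1, 0.0, 0.1]),
                             {(0, 2): 0.5})
        p = tmp_path / "w.json"
        w.to_json(p, S)
        back, S_back = lm.FactorWeights.from_json(p)
        np.testing.assert_allclose(back.acc, w.acc)
        np.testing.assert_allclose(back.lab, w.lab)
        assert back.corr == w.corr
        assert S_back.pairs == S.pairs
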