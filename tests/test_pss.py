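"""Attention-weight computation and the three masking strategies."""

import itertools
import math

import numpy as np
import pytest

from claps.pss import (MaskPlan, PSSNetwork, WeightVector, apply_mask,
                       attention_matrix, occurrence_weights, random_mask,
                       roulette_mask, top_mask, weight_vector)
from claps.smiles_data import build_vocabulary, encode


def brute_force_attention(X, Wq, Wk, d):
    """Dense-loop softmax attention oracle for one head."""
    L = X.shape[0]
    Q, K = X @ Wq, X @ Wk
    att = np.zeros((L, L))
    for r in range(L):
        scores = [Q[r] @ K[c] / math.sqrt(d) for c in range(L)]
        e = np.exp(np.array(scores) - max(scores))
        att[r] = e / e.sum()
    return att


class TestAttention:
    def test_identical_rows_give_uniform_attention(self, rng):
        d = 12
        net = PSSNetwork(d, heads=3, layers=1, seed=0)
        X = np.tile(rng.normal(0, 1, (1, d)), (5, 1))
        att = attention_matrix(X, net, true_length=5)
        np.testing.assert_allclose(att, 1.0 / 5, atol=1e-12)

    def test_length_one_is_trivial(self, rng):
        net = PSSNetwork(8, heads=2, layers=2, seed=1)
        att = attention_matrix(rng.normal(0, 1, (4, 8)), net, true_length=1)
        np.testing.assert_allclose(att, np.ones((2, 1, 1)))

    def test_matches_dense_loop_oracle_single_head(self, rng):
        d = 10
        net = PSSNetwork(d, heads=1, layers=1, seed=2)
        X = rng.normal(0, 1, (3, d))
        att = attention_matrix(X, net, true_length=3)
        ref = brute_force_attention(X, net.W_q[0][0], net.W_k[0][0], d)
        np.testing.assert_allclose(att[0], ref, atol=1e-12)

    def test_rows_are_probability_vectors(self, rng):
        net = PSSNetwork(16, heads=3, layers=2, seed=3)
        for _ in range(20):
            L = int(rng.integers(2, 12))
            att = attention_matrix(rng.normal(0, 1, (L + 2, 16)), net, L)
            assert att.shape == (3, L, L)
            assert np.all(att >= 0)
            np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_length_rejected(self, rng):
        net = PSSNetwork(8, heads=1, layers=1, seed=0)
        with pytest.raises(ValueError):
            attention_matrix(rng.normal(0, 1, (3, 8)), net, true_length=0)


class TestWeightVector:
    def test_uniform_attention_three_heads(self):
        att = np.full((3, 4, 4), 0.25)
        w = weight_vector(att)
        np.testing.assert_allclose(w.weights, [3, 3, 3, 3])

    def test_single_head_single_char(self):
        np.testing.assert_allclose(weight_vector(np.ones((1, 1, 1))).weights, [1])

    def test_matches_double_loop_oracle(self, rng):
        raw = rng.random((3, 5, 5))
        att = raw / raw.sum(axis=-1, keepdims=True)
        w = weight_vector(att)
        for r in range(5):
            expected = sum(att[h, r, c] for h in range(3) for c in range(5))
            assert w.weights[r] == pytest.approx(expected, abs=1e-12)

    def test_conservation_law(self, rng):
        net = PSSNetwork(16, heads=3, layers=2, seed=5)
        for _ in range(25):
            L = int(rng.integers(1, 15))
            att = attention_matrix(rng.normal(0, 1, (L, 16)), net, L)
            total = weight_vector(att).weights.sum()
            assert total == pytest.approx(3 * L, abs=1e-5)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(weights=np.array([1.0, -0.1]))


class TestRouletteMask:
    def test_single_draw_probability(self, rng):
        w = WeightVector(weights=np.array([0.7, 0.1, 0.1, 0.1]))
        hits = sum(0 in roulette_mask(w, 0.25, rng).positions
                   for _ in range(20000))
        assert hits / 20000 == pytest.approx(0.7, abs=0.02)

    def test_uniform_weights_symmetric(self, rng):
        w = WeightVector(weights=np.ones(4))
        counts = np.zeros(4)
        for _ in range(20000):
            for p in roulette_mask(w, 0.25, rng).positions:
                counts[p] += 1
        np.testing.assert_allclose(counts / 20000, 0.25, atol=0.02)

    def test_inclusion_matches_enumeration_oracle(self, rng):
        # exact inclusion probabilities for 2-of-3 draws without replacement
        w = np.array([5.0, 3.0, 2.0])
        incl = np.zeros(3)
        for i, j in itertools.permutations(range(3), 2):
            p = (w[i] / w.sum()) * (w[j] / (w.sum() - w[i]))
            incl[i] += p
            incl[j] += p
        counts = np.zeros(3)
        trials = 30000
        for _ in range(trials):
            for p in roulette_mask(WeightVector(weights=w), 2 / 3, rng).positions:
                counts[p] += 1
        np.testing.assert_allclose(counts / trials, incl, atol=0.02)

    def test_draws_without_replacement_and_count(self, rng):
        w = WeightVector(weights=np.array([5.0, 3.0, 2.0]))
        plan = roulette_mask(w, 2 / 3, rng)
        assert len(plan.positions) == 2
        assert plan.positions <= {0, 1, 2}

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            roulette_mask(WeightVector(weights=np.zeros(3)), 0.5, rng)

    def test_reproducible_under_seed(self):
        w = WeightVector(weights=np.array([1.0, 2.0, 3.0, 4.0]))
        a = roulette_mask(w, 0.5, np.random.default_rng(9)).positions
        b = roulette_mask(w, 0.5, np.random.default_rng(9)).positions
        assert a == b


class TestTopMask:
    @pytest.mark.parametrize("ratio,expected", [
        (0.25, {0}), (0.5, {0, 1}),
    ])
    def test_largest_weights_selected(self, ratio, expected):
        w = WeightVector(weights=np.array([0.4, 0.3, 0.2, 0.1]))
        assert top_mask(w, ratio).positions == expected

    def test_ties_go_to_lower_index(self):
        w = WeightVector(weights=np.array([2.0, 1.0, 1.0]))
        assert top_mask(w, 1 / 3).positions == {0}
        assert top_mask(w, 2 / 3).positions == {0, 1}

    def test_monotone_nesting(self, rng):
        w = WeightVector(weights=rng.random(9))
        ratios = [0.1, 0.25, 0.4, 0.6, 0.8, 0.95]
        plans = [top_mask(w, r).positions for r in ratios]
        for small, big in zip(plans, plans[1:]):
            assert small <= big


class TestRandomMask:
    def test_exact_count_and_range(self, rng):
        plan = random_mask(4, 0.5, rng)
        assert len(plan.positions) == 2
        assert plan.positions <= {0, 1, 2, 3}

    def test_uniform_frequencies(self, rng):
        counts = np.zeros(4)
        for _ in range(20000):
            for p in random_mask(4, 0.25, rng).positions:
                counts[p] += 1
        np.testing.assert_allclose(counts / 20000, 0.25, atol=0.02)

    def test_seeded_determinism(self):
        a = random_mask(10, 0.3, np.random.default_rng(4)).positions
        b = random_mask(10, 0.3, np.random.default_rng(4)).positions
        assert a == b

    @pytest.mark.parametrize("ratio", [0.0, 1.0, -0.2])
    def test_ratio_bounds_enforced(self, rng, ratio):
        with pytest.raises(ValueError):
            random_mask(5, ratio, rng)


class TestApplyMask:
    def setup_method(self):
        self.vocab = build_vocabulary(["CCO", "CCN"])
        self.mol = encode("CCO", self.vocab, C=6)

    def test_empty_plan_is_identity(self):
        plan = MaskPlan(positions=frozenset(), ratio=0.5, strategy="top")
        out = apply_mask(self.mol, plan, self.vocab)
        np.testing.assert_array_equal(out.token_ids, self.mol.token_ids)

    def test_masked_position_replaced_by_mask_id(self):
        plan = MaskPlan(positions=frozenset({0}), ratio=0.25, strategy="top")
        out = apply_mask(self.mol, plan, self.vocab)
        assert out.token_ids[0] == self.vocab.mask_id
        np.testing.assert_array_equal(out.token_ids[1:], self.mol.token_ids[1:])
        assert out.true_length == self.mol.true_length

    def test_masked_count_matches_plan(self, rng):
        plan = random_mask(3, 2 / 3, rng)
        out = apply_mask(self.mol, plan, self.vocab)
        assert (out.token_ids == self.vocab.mask_id).sum() == len(plan.positions)

    def test_position_beyond_true_length_rejected(self):
        plan = MaskPlan(positions=frozenset({4}), ratio=0.5, strategy="random")
        with pytest.raises(IndexError):
            apply_mask(self.mol, plan, self.vocab)


def test_occurrence_weights_count_token_types():
    w = occurrence_weights("CCO")
    np.testing.assert_allclose(w.weights, [2, 2, 1])
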