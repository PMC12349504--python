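"""Pairwise matching loss, BCE and the composite objective."""

import numpy as np
import pytest

from pestpair import (
    bce_loss,
    make_pair_set,
    pair_indicators,
    pairwise_matching_loss,
    total_loss,
)
from pestpair.losses import PairSet
from pestpair.nn import AdamW, Parameter, Tensor


def loop_pair_loss(p, y_set, pairs, eps=1e-7, negate=True):
    """Explicit double-loop evaluation of the pairwise matching sum."""
    total = 0.0
    for i, j in pairs.pairs:
        y = 1.0 if (i in y_set and j in y_set) else 0.0
        pij = min(max(p[i] * p[j], eps), 1 - eps)
        total += y * np.log(pij) + (1 - y) * np.log(1 - pij)
    return -total if negate else total


class TestPairIndicators:
    def test_basic_pair_membership(self):
        ps = make_pair_set(3)
        assert np.array_equal(pair_indicators({0, 1}, ps), [1, 0, 0])

    def test_empty_label_set(self):
        ps = make_pair_set(4)
        assert pair_indicators(set(), ps).sum() == 0

    def test_full_label_set(self):
        ps = make_pair_set(4)
        assert np.all(pair_indicators({0, 1, 2, 3}, ps) == 1)

    def test_multihot_batch_matches_sets(self):
        ps = make_pair_set(5)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, (20, 5))
        batch = pair_indicators(labels, ps)
        for b in range(20):
            expected = pair_indicators(set(np.flatnonzero(labels[b])), ps)
            assert np.array_equal(batch[b], expected)

    def test_pair_set_validation(self):
        with pytest.raises(ValueError, match="i < j"):
            PairSet(((2, 1),))
        with pytest.raises(ValueError, match="duplicate"):
            PairSet(((0, 1), (0, 1)))

    def test_predator_pest_mode(self, schema):
        ps = make_pair_set(8, "predator_pest", schema)
        assert len(ps) == 16
        roles = [c.role for c in schema.categories]
        for i, j in ps.pairs:
            assert {roles[i], roles[j]} == {"predator", "pest"}


class TestPairwiseMatchingLoss:
    def test_hand_derived_case(self):
        ps = make_pair_set(3)
        val = pairwise_matching_loss(np.array([0.9, 0.8, 0.1]), {0, 1}, ps)
        expected = -(np.log(0.72) + np.log(1 - 0.09) + np.log(1 - 0.08))
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(0.50620, abs=1e-4)

    def test_perfect_predictions_zero_loss(self):
        ps = make_pair_set(3)
        # eps-clamping keeps the loss within ~C^2 * eps of zero
        assert pairwise_matching_loss(np.array([1.0, 1.0, 0.0]), {0, 1}, ps) < 1e-5

    def test_clamped_product_is_finite(self):
        ps = PairSet(((0, 1),))
        eps = 1e-7
        val = pairwise_matching_loss(np.array([0.0, 0.0]), {0, 1}, ps, eps=eps)
        assert val == pytest.approx(-np.log(eps), rel=1e-9)

    def test_printed_sign_flag(self):
        ps = make_pair_set(3)
        p = np.array([0.9, 0.8, 0.1])
        assert pairwise_matching_loss(p, {0, 1}, ps, negate=False) == pytest.approx(
            -pairwise_matching_loss(p, {0, 1}, ps), abs=1e-12
        )

    def test_out_of_range_probabilities_rejected(self):
        ps = make_pair_set(2)
        with pytest.raises(ValueError, match="probabilities"):
            pairwise_matching_loss(np.array([1.2, 0.5]), {0}, ps)

    def test_invalid_eps_rejected(self):
        ps = make_pair_set(2)
        with pytest.raises(ValueError, match="eps"):
            pairwise_matching_loss(np.array([0.5, 0.5]), {0}, ps, eps=0.0)

    def test_mean_reduction_divides_by_pair_count(self):
        ps = make_pair_set(4)
        p = np.array([0.7, 0.6, 0.2, 0.9])
        s = pairwise_matching_loss(p, {0, 3}, ps, reduction="sum")
        m = pairwise_matching_loss(p, {0, 3}, ps, reduction="mean")
        assert m == pytest.approx(s / len(ps), rel=1e-12)

    def test_vectorized_matches_loop_oracle(self):
        """1000 random instances, C <= 6, agreement to 1e-9."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            c = int(rng.integers(2, 7))
            ps = make_pair_set(c)
            p = rng.random(c)
            y_set = set(np.flatnonzero(rng.integers(0, 2, c)))
            vec = pairwise_matching_loss(p, y_set, ps)
            assert abs(vec - loop_pair_loss(p, y_set, ps)) < 1e-9

    def test_tensor_path_matches_numpy_path(self):
        rng = np.random.default_rng(5)
        ps = make_pair_set(6)
        p = rng.random(6).astype(np.float32)
        y = pair_indicators(set(np.flatnonzero(rng.integers(0, 2, 6))), ps)
        t = pairwise_matching_loss(Tensor(p.copy()), y, ps)
        n = pairwise_matching_loss(p.astype(np.float64), y, ps)
        assert float(t.data) == pytest.approx(n, rel=1e-4)

    def test_gradient_signs_by_finite_differences(self):
        """Co-occurring pairs reward raising p_i; absent pairs punish it."""
        ps = PairSet(((0, 1),))
        h = 1e-6

        def loss_at(p0, y_set):
            return pairwise_matching_loss(np.array([p0, 0.6]), y_set, ps)

        d_cooc = (loss_at(0.5 + h, {0, 1}) - loss_at(0.5 - h, {0, 1})) / (2 * h)
        assert d_cooc < 0
        d_not = (loss_at(0.5 + h, {1}) - loss_at(0.5 - h, {1})) / (2 * h)
        assert d_not > 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_optimizing_pair_loss_induces_positive_covariance(self, seed):
        """Minimising the pairwise loss on planted co-occurrences makes the
        two probabilities positively covary across samples."""
        rng = np.random.default_rng(seed)
        n = 40
        y_pair = rng.integers(0, 2, (n, 1)).astype(np.float64)  # planted pattern
        logits = Parameter(0.1 * rng.standard_normal((n, 2)))
        ps = PairSet(((0, 1),))
        opt = AdamW([logits], lr=0.2, weight_decay=0.0)
        for _ in range(150):
            opt.zero_grad()
            loss = pairwise_matching_loss(logits.sigmoid(), y_pair, ps, reduction="mean")
            loss.backward()
            opt.step()
        p = 1 / (1 + np.exp(-logits.data))
        cov = np.cov(p[:, 0], p[:, 1])[0, 1]
        assert cov >= 0

    def test_non_negative_under_negation(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            c = int(rng.integers(2, 6))
            ps = make_pair_set(c)
            p = rng.random(c)
            y_set = set(np.flatnonzero(rng.integers(0, 2, c)))
            assert pairwise_matching_loss(p, y_set, ps) >= 0


class TestBceLoss:
    def test_hand_derived_case(self):
        val = bce_loss(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0]))
        assert val == pytest.approx(-(np.log(0.9) + np.log(0.8) + np.log(0.9)), abs=1e-12)
        assert val == pytest.approx(0.43386, abs=1e-4)

    def test_exact_predictions_zero_loss(self):
        assert bce_loss(np.array([1.0, 0.0, 1.0]), np.array([1, 0, 1])) < 1e-5

    def test_soft_target_minimum_is_entropy(self):
        t = 0.25
        at_t = bce_loss(np.array([t]), np.array([t]))
        entropy = -(t * np.log(t) + (1 - t) * np.log(1 - t))
        assert at_t == pytest.approx(entropy, rel=1e-9)
        for p in [0.1, 0.2, 0.3, 0.6]:
            assert bce_loss(np.array([p]), np.array([t])) > at_t

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError, match="targets"):
            bce_loss(np.array([0.5]), np.array([1.5]))


class TestTotalLoss:
    def test_worked_composition(self):
        lb = total_loss(0.43386, 0.50620, 0.4)
        assert lb.l_total == pytest.approx(0.63634, abs=1e-4)

    def test_lambda_zero_is_bce_only(self):
        lb = total_loss(0.7, 123.0, 0.0)
        assert lb.l_total == 0.7

    def test_zero_pair_loss(self):
        lb = total_loss(0.7, 0.0, 0.4)
        assert lb.l_total == 0.7

    def test_breakdown_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            b, p, lam = rng.random(3)
            lb = total_loss(b, p, lam)
            assert lb.l_total == pytest.approx(lb.l_bce + lb.lam * lb.l_pair, abs=1e-9)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            total_loss(0.5, 0.5, -0.1)
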