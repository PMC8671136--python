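import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eiic.losses import (
    IicConfig,
    _iic_pair_loss_grads,
    complement_distribution,
    cross_entropy,
    iic_loss,
    joint_assignment,
    marginal_entropy,
    mutual_information_lambda,
    prior_pair_loss,
)
from eiic.network import softmax_backward


def _softmax(z):
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _random_joint(rng, c=3):
    """Random symmetrized joint assignment from softmax batches."""
    phi1 = _softmax(rng.normal(size=(8, c)))
    phi2 = _softmax(rng.normal(size=(8, c)))
    return joint_assignment(phi1, phi2)


class TestJointAssignment:
    def test_one_hot_outer_product(self):
        p = joint_assignment([[1.0, 0.0]], [[1.0, 0.0]])
        np.testing.assert_allclose(p, [[1, 0], [0, 0]], atol=1e-12)

    def test_symmetrized_cross_pairs(self):
        p = joint_assignment([[1, 0], [0, 1]], [[0, 1], [1, 0]], symmetrize=True)
        np.testing.assert_allclose(p, [[0, 0.5], [0.5, 0]], atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_assignment([[1, 0]], [[1, 0, 0]])

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            joint_assignment([[0.5, 0.2]], [[1, 0]])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_always_a_distribution_over_pairs(self, seed):
        p = _random_joint(np.random.default_rng(seed))
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(p - p.T)) < 1e-12


class TestMarginalEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1.0, 0.0], 0.0),
            ([0.5, 0.5], math.log(2)),
            ([0.25] * 4, math.log(4)),
        ],
    )
    def test_closed_forms(self, p, expected):
        assert marginal_entropy(p) == pytest.approx(expected, abs=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            marginal_entropy([-0.1, 1.1])


class TestMutualInformation:
    def test_independent_uniform_is_zero(self):
        p = np.full((2, 2), 0.25)
        assert mutual_information_lambda(p, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_closed_forms(self):
        p = np.diag([0.5, 0.5])
        assert mutual_information_lambda(p, 1.0) == pytest.approx(math.log(2), abs=1e-7)
        assert mutual_information_lambda(p, 5.0) == pytest.approx(9 * math.log(2), abs=1e-6)

    def test_matches_bruteforce_double_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = _random_joint(rng, c=rng.integers(2, 5))
            lam = float(rng.uniform(1.0, 6.0))
            pr, pc = p.sum(axis=1), p.sum(axis=0)
            brute = 0.0
            for c in range(p.shape[0]):
                for cp in range(p.shape[1]):
                    brute += p[c, cp] * (
                        math.log(p[c, cp] + 1e-12)
                        - lam * math.log(pr[c] + 1e-12)
                        - lam * math.log(pc[cp] + 1e-12)
                    )
            assert mutual_information_lambda(p, lam) == pytest.approx(brute, abs=1e-10)

    def test_nonnegative_at_lambda_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert mutual_information_lambda(_random_joint(rng), 1.0) >= -1e-10


class TestIicLoss:
    @pytest.mark.parametrize(
        "p, lam, expected",
        [
            (np.diag([0.5, 0.5]), 1.0, -1.0),
            (np.full((2, 2), 0.25), 1.0, 0.0),
            (np.full((2, 2), 0.25), 5.0, -8.0),
            (np.diag([0.5, 0.5]), 5.0, -9.0),
        ],
    )
    def test_two_class_closed_forms(self, p, lam, expected):
        assert iic_loss(p, lam) == pytest.approx(expected, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            iic_loss(np.array([[1.0]]), 1.0)

    def test_bounded_at_lambda_one(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = _random_joint(rng)
            assert -1.0 - 1e-10 <= iic_loss(p, 1.0) <= 1e-10

    def test_grid_search_minimizer_is_balanced_diagonal(self):
        """Brute-force over symmetric 2x2 joints at resolution 0.01."""
        lam = 5.0
        best, argbest = np.inf, None
        for a in np.arange(0.0, 1.0001, 0.01):
            for c in np.arange(0.0, 1.0001 - a, 0.01):
                b = (1.0 - a - c) / 2.0
                p = np.array([[a, b], [b, c]])
                val = iic_loss(p, lam)
                if val < best:
                    best, argbest = val, (a, c)
        assert best == pytest.approx(-(2 * lam - 1), abs=1e-6)
        # the minimum is attained only by the two perfectly-coupled balanced
        # joints: diag(1/2, 1/2) and its anti-diagonal mirror (a = c = 0)
        assert argbest in ((0.5, 0.5), (0.0, 0.0))
        assert iic_loss(np.diag([0.5, 0.5]), lam) == pytest.approx(best, abs=1e-6)


class TestComplement:
    def test_swaps_two_class_probabilities(self):
        np.testing.assert_allclose(complement_distribution([0.3, 0.7]), [0.7, 0.3])
        np.testing.assert_allclose(complement_distribution([1.0, 0.0]), [0.0, 1.0])

    def test_involution(self):
        rng = np.random.default_rng(3)
        phi = _softmax(rng.normal(size=(10, 2)))
        np.testing.assert_allclose(
            complement_distribution(complement_distribution(phi)), phi, atol=1e-12
        )

    def test_only_defined_for_two_classes(self):
        with pytest.raises(ValueError):
            complement_distribution([0.2, 0.3, 0.5])


class TestCrossEntropy:
    def test_closed_forms(self):
        assert cross_entropy(np.array([1.0, 0.0]), 0) == pytest.approx(0.0, abs=1e-9)
        assert cross_entropy(np.array([0.5, 0.5]), 1) == pytest.approx(math.log(2), abs=1e-9)
        assert cross_entropy(np.array([0.25, 0.75]), 1) == pytest.approx(
            math.log(4 / 3), abs=1e-9
        )

    def test_nonnegative_and_zero_iff_one_hot(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            phi = _softmax(rng.normal(size=2))
            assert cross_entropy(phi, 1) >= 0.0
        assert cross_entropy(np.array([0.0, 1.0]), 1) < 1e-9


class TestPriorPairLoss:
    def _identity_heads(self):
        return {"iic": lambda x: np.asarray(x), "iic_oc": lambda x: np.asarray(x)}

    def test_different_label_pairs_via_complement(self):
        # complemented second members align with the first: joint diag(0.5, 0.5)
        x1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        x2 = np.array([[0.0, 1.0], [1.0, 0.0]])
        cfg = IicConfig(lambda_weight=1.0)
        total = prior_pair_loss(None, (x1, x2), self._identity_heads(), cfg)
        assert total == pytest.approx(-1.0, abs=1e-6)

    def test_same_label_pairs_hit_both_heads(self):
        main = np.array([[1.0, 0.0], [0.0, 1.0]])
        oc = np.eye(10)[:2]

        heads = {
            "iic": lambda x: np.asarray(x)[:, :2],
            "iic_oc": lambda x: np.eye(10)[np.argmax(np.asarray(x), axis=1)],
        }
        cfg = IicConfig(lambda_weight=1.0)
        total = prior_pair_loss((main, main), None, heads, cfg)
        # main head: diagonal joint over 2 classes -> -1; oc head: diagonal
        # joint over 2 of 10 classes -> -(ln 2)/ln 10
        assert total == pytest.approx(-1.0 - math.log(2) / math.log(10), abs=1e-6)
        assert oc.shape == (2, 10)

    def test_empty_diff_group_is_additive_identity(self):
        main = np.array([[1.0, 0.0], [0.0, 1.0]])
        heads = self._identity_heads()
        cfg = IicConfig(lambda_weight=1.0)
        same_only = prior_pair_loss((main, main), None, heads, cfg)
        both = prior_pair_loss((main, main), (main[:0], main[:0]), heads, cfg)
        assert both == pytest.approx(same_only)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            prior_pair_loss(None, None, self._identity_heads(), IicConfig())


def test_pair_loss_gradient_matches_finite_differences():
    """Analytic gradient through softmax vs numerical differentiation."""
    rng = np.random.default_rng(0)
    n, c, lam = 6, 3, 5.0
    z1, z2 = rng.normal(size=(n, c)), rng.normal(size=(n, c))

    def loss_of(za, zb):
        return _iic_pair_loss_grads(_softmax(za), _softmax(zb), lam)[0]

    p1, p2 = _softmax(z1), _softmax(z2)
    base, d1, d2 = _iic_pair_loss_grads(p1, p2, lam)
    g1, g2 = softmax_backward(p1, d1), softmax_backward(p2, d2)
    eps = 1e-6
    for which, (z, g) in enumerate(((z1, g1), (z2, g2))):
        for i in range(n):
            for k in range(c):
                za, zb = z1.copy(), z2.copy()
                (za if which == 0 else zb)[i, k] += eps
                num = (loss_of(za, zb) - base) / eps
                assert num == pytest.approx(g[i, k], abs=5e-5)
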