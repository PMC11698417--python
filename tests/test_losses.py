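"""Loss components: worked scalar cases, invariants, and analytic-vs-
finite-difference gradients."""

import numpy as np
import pytest

from octlayers.losses import (LossConfig, boundary_mse, dice_loss,
                              onehot_encode, total_loss,
                              weighted_cross_entropy)
from octlayers.nn import Tensor


def softmax_np(x, axis=1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        y = onehot_encode(np.array([[0, 1], [1, 0]]), 2)
        w = np.ones((1, 2, 2))
        val = weighted_cross_entropy(y, y, w).item()
        assert 0 <= val < 1e-5

    def test_uniform_binary_one_pixel(self):
        """Uniform prediction over K=2 on a single pixel: CE = ln 2."""
        p = np.full((1, 2, 1, 1), 0.5)
        y = onehot_encode(np.zeros((1, 1, 1), dtype=int), 2)
        w = np.ones((1, 1, 1))
        assert weighted_cross_entropy(p, y, w).item() == pytest.approx(
            np.log(2), rel=1e-5)

    def test_linear_in_weights(self, rng):
        p = softmax_np(rng.normal(size=(2, 3, 4, 4)))
        y = onehot_encode(rng.integers(0, 3, (2, 4, 4)), 3)
        w = rng.uniform(0.5, 1.5, (2, 4, 4))
        one = weighted_cross_entropy(p, y, w).item()
        two = weighted_cross_entropy(p, y, 2 * w).item()
        assert two == pytest.approx(2 * one, rel=1e-6)

    def test_unweighted_equals_w1(self, rng):
        p = softmax_np(rng.normal(size=(2, 3, 4, 4)))
        y = onehot_encode(rng.integers(0, 3, (2, 4, 4)), 3)
        w = np.ones((2, 4, 4))
        assert weighted_cross_entropy(p, y, w).item() >= 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            weighted_cross_entropy(np.ones((1, 2, 2, 2)) / 2,
                                   np.ones((1, 2, 2, 2)), np.ones((1, 3, 3)))


class TestDiceLoss:
    def test_perfect_overlap_zero(self):
        y = onehot_encode(np.array([[0, 1, 1]]), 2)
        assert dice_loss(y, y).item() == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_contributes_one(self):
        # class 1: prediction and truth disjoint -> contributes 1
        y = np.zeros((1, 2, 1, 4))
        y[0, 1, 0, :2] = 1
        y[0, 0, 0, 2:] = 1
        p = np.zeros((1, 2, 1, 4))
        p[0, 1, 0, 2:] = 1
        p[0, 0, 0, :2] = 1
        assert dice_loss(p, y).item() == pytest.approx(2.0, abs=1e-6)

    def test_half_overlap_worked_case(self):
        """y covers 2 pixels; p puts 0.5 on the same 2 pixels:
        1 - 2*1/(2+1) = 1/3 for that class."""
        y = np.zeros((1, 1, 1, 4))
        y[0, 0, 0, :2] = 1.0
        p = np.zeros((1, 1, 1, 4))
        p[0, 0, 0, :2] = 0.5
        assert dice_loss(p, y).item() == pytest.approx(1 / 3, rel=1e-5)

    def test_bounded_by_nk(self, rng):
        p = softmax_np(rng.normal(size=(3, 4, 5, 5)))
        y = onehot_encode(rng.integers(0, 4, (3, 5, 5)), 4)
        val = dice_loss(p, y).item()
        assert 0 <= val <= 3 * 4


class TestBoundaryMse:
    def test_exact_regression_zero(self, rng):
        t = rng.uniform(-1, 1, (2, 3, 4, 4))
        w = np.ones((2, 4, 4))
        assert boundary_mse(t, t, w).item() == 0.0

    def test_single_pixel_case(self):
        assert boundary_mse(np.full((1, 1, 1, 1), 0.5),
                            np.zeros((1, 1, 1, 1)),
                            np.ones((1, 1, 1))).item() == pytest.approx(0.25)

    def test_linear_in_weights(self, rng):
        s = rng.uniform(-1, 1, (1, 2, 3, 3))
        d = rng.uniform(-1, 1, (1, 2, 3, 3))
        w = np.ones((1, 3, 3))
        assert boundary_mse(s, d, 2 * w).item() == pytest.approx(
            2 * boundary_mse(s, d, w).item(), rel=1e-6)


class TestTotalLoss:
    def test_lambda_zero_decouples(self, rng):
        mask = rng.integers(0, 3, (1, 8, 8))
        seg = softmax_np(rng.normal(size=(1, 3, 8, 8)))
        pred = rng.uniform(-1, 1, (1, 3, 8, 8))
        cfg0 = LossConfig(lambda_bou=0.0)
        tot, parts = total_loss(seg, pred, mask, cfg0)
        assert tot.item() == pytest.approx(parts["ce"] + parts["dice"],
                                           rel=1e-9)

    def test_adaptive_off_matches_unweighted(self, rng):
        mask = rng.integers(0, 3, (1, 8, 8))
        seg = softmax_np(rng.normal(size=(1, 3, 8, 8)))
        pred = rng.uniform(-1, 1, (1, 3, 8, 8))
        cfg = LossConfig(use_adaptive_weight=False)
        _, parts = total_loss(seg, pred, mask, cfg)
        y = onehot_encode(mask, 3)
        w = np.ones((1, 8, 8))
        assert parts["ce"] == pytest.approx(
            weighted_cross_entropy(seg, y, w).item(), rel=1e-9)

    def test_joint_optimum_near_zero(self):
        from octlayers.tsdf import tsdf_stack
        mask = np.zeros((8, 8), dtype=int)
        mask[4:] = 1
        seg = onehot_encode(mask, 2) * (1 - 2e-7) + 1e-7
        target = tsdf_stack(mask, 2, 5.0).values[None]
        tot, _ = total_loss(seg, target, mask, LossConfig(),
                            target_tsdf=target)
        assert tot.item() == pytest.approx(0.0, abs=1e-4)

    def test_nonnegative_components(self, rng):
        mask = rng.integers(0, 4, (2, 8, 8))
        seg = softmax_np(rng.normal(size=(2, 4, 8, 8)))
        pred = rng.uniform(-1, 1, (2, 4, 8, 8))
        _, parts = total_loss(seg, pred, mask, LossConfig())
        assert all(v >= 0 for v in parts.values())


def central_diff(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


class TestGradients:
    """Analytic gradients match central finite differences to 1e-4."""

    def test_weighted_ce_gradient(self, rng):
        logits = rng.normal(size=(1, 3, 2, 2))
        y = onehot_encode(rng.integers(0, 3, (1, 2, 2)), 3)
        w = rng.uniform(0.5, 1.5, (1, 2, 2))

        def f(lg):
            return weighted_cross_entropy(softmax_np(lg), y, w).item()

        t = Tensor(logits, requires_grad=True)
        from octlayers.nn import softmax as t_softmax
        loss = weighted_cross_entropy(t_softmax(t, axis=1), y, w)
        loss.backward()
        np.testing.assert_allclose(t.grad, central_diff(f, logits),
                                   rtol=1e-4, atol=1e-8)

    def test_dice_gradient(self, rng):
        probs = rng.uniform(0.1, 0.9, (1, 2, 2, 2))
        y = onehot_encode(rng.integers(0, 2, (1, 2, 2)), 2)

        def f(p):
            return dice_loss(p, y).item()

        t = Tensor(probs, requires_grad=True)
        dice_loss(t, y).backward()
        np.testing.assert_allclose(t.grad, central_diff(f, probs),
                                   rtol=1e-4, atol=1e-8)

    def test_boundary_mse_gradient(self, rng):
        pred = rng.uniform(-1, 1, (1, 2, 2, 2))
        target = rng.uniform(-1, 1, (1, 2, 2, 2))
        w = rng.uniform(0.5, 1.5, (1, 2, 2))

        def f(s):
            return boundary_mse(s, target, w).item()

        t = Tensor(pred, requires_grad=True)
        boundary_mse(t, target, w).backward()
        np.testing.assert_allclose(t.grad, central_diff(f, pred),
                                   rtol=1e-4, atol=1e-8)

    def test_weight_map_is_detached(self, rng):
        """The adaptive weight map never carries gradient: perturbing the
        predicted TSDF changes the boundary-loss gradient only through the
        multiplicative factor, so gradients with a frozen (precomputed)
        weight map equal gradients with the recomputed one."""
        mask = rng.integers(0, 3, (1, 6, 6))
        seg_np = softmax_np(rng.normal(size=(1, 3, 6, 6)))
        pred_np = rng.uniform(-1, 1, (1, 3, 6, 6))
        cfg = LossConfig(weight_source="predicted")

        pred_t = Tensor(pred_np, requires_grad=True)
        tot, _ = total_loss(seg_np, pred_t, mask, cfg)
        tot.backward()
        g_recomputed = pred_t.grad.copy()

        from octlayers.losses import _weight_map
        from octlayers.tsdf import tsdf_stack
        target = np.stack([tsdf_stack(mask[0], 3, cfg.tau).values])
        w_frozen = _weight_map(pred_np, target, cfg)
        pred_t2 = Tensor(pred_np, requires_grad=True)
        loss2 = boundary_mse(pred_t2, target, w_frozen) * cfg.lambda_bou
        loss2.backward()
        np.testing.assert_allclose(g_recomputed, pred_t2.grad, atol=1e-10)
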