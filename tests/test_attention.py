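"""The attention module: oracle equivalence, invariants, differentiability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import structured_cells
from gridattn.attention import (
    AttentionConfig,
    AttentionMap,
    AttentionModel,
    attend,
    classify,
    compute_attention_logits,
    normalize_attention,
)
from gridattn.backbone import GridTensor, extract_features, make_backbone
from gridattn.nn import cross_entropy
from gridattn.preprocessing import GridShape


def brute_force_attention_logits(U, W, b):
    """Triple-nested-loop oracle for the 3-D attention convolution."""
    F, k, d, _ = W.shape
    r, c, _ = U.shape
    h = d // 2
    out = np.zeros((F, r, c))
    for f in range(F):
        for i in range(r):
            for j in range(c):
                s = b[f]
                for kk in range(k):
                    for a in range(-h, h + 1):
                        for bb_ in range(-h, h + 1):
                            ii, jj = i + a, j + bb_
                            if 0 <= ii < r and 0 <= jj < c:
                                s += W[f, kk, a + h, bb_ + h] * U[ii, jj, kk]
                out[f, i, j] = s
    return out


def brute_force_attend(U, alpha):
    F = alpha.shape[0]
    r, c, k = U.shape
    z = np.zeros((F, k))
    for f in range(F):
        for i in range(r):
            for j in range(c):
                z[f] += alpha[f, i, j] * U[i, j]
    return z.reshape(-1)


class TestAttentionLogits:
    def test_matches_brute_force_oracle(self, rng):
        r, c, k, F = 4, 5, 8, 3
        U = rng.normal(size=(r, c, k)).astype(np.float32)
        W = rng.normal(size=(F, k, 3, 3)).astype(np.float32)
        b = rng.normal(size=F).astype(np.float32)
        got = compute_attention_logits(GridTensor(U, GridShape(r, c), k), W, b)
        assert np.abs(got - brute_force_attention_logits(U, W, b)).max() <= 1e-5

    def test_zero_filters_give_zero_logits(self, rng):
        U = rng.normal(size=(3, 3, 4)).astype(np.float32)
        W = np.zeros((2, 4, 3, 3), np.float32)
        got = compute_attention_logits(U, W, np.zeros(2, np.float32))
        np.testing.assert_allclose(got, 0.0, atol=1e-7)

    def test_zero_grid_gives_bias_everywhere(self, rng):
        U = np.zeros((2, 4, 5), np.float32)
        W = rng.normal(size=(3, 5, 3, 3)).astype(np.float32)
        b = np.array([0.5, -1.0, 2.0], np.float32)
        got = compute_attention_logits(U, W, b)
        for f in range(3):
            np.testing.assert_allclose(got[f], b[f], atol=1e-6)

    def test_depth_mismatch_rejected(self, rng):
        U = rng.normal(size=(2, 2, 4)).astype(np.float32)
        with pytest.raises(ValueError, match="depth"):
            compute_attention_logits(U, rng.normal(size=(1, 5, 3, 3)))


class TestNormalizeAttention:
    def test_constant_logits_give_uniform_weights(self):
        amap = normalize_attention(np.full((2, 2, 3), 1.7, np.float32))
        np.testing.assert_allclose(amap.alpha, 1 / 6, atol=1e-6)

    def test_hand_computed_softmax(self):
        amap = normalize_attention(np.array([[[0.0, np.log(3.0)]]], np.float32))
        np.testing.assert_allclose(amap.alpha[0, 0], [0.25, 0.75], atol=1e-6)

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=(4, 3, 5)).astype(np.float32)
        a1 = normalize_attention(logits).alpha
        a2 = normalize_attention(logits + 100.0).alpha
        np.testing.assert_allclose(a1, a2, atol=1e-5)

    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_heads_always_sum_to_one(self, r, c, seed):
        logits = np.random.default_rng(seed).normal(0, 5, size=(3, r, c))
        amap = normalize_attention(logits.astype(np.float32))
        np.testing.assert_allclose(amap.alpha.sum(axis=(1, 2)), 1.0, atol=1e-5)
        assert (amap.alpha >= 0).all()


class TestAttend:
    def test_equal_cells_give_that_vector_for_any_alpha(self, rng):
        v = rng.normal(size=5).astype(np.float32)
        U = np.broadcast_to(v, (2, 3, 5)).copy()
        alpha = normalize_attention(rng.normal(size=(4, 2, 3)).astype(np.float32))
        z = attend(U, alpha).reshape(4, 5)
        for f in range(4):
            np.testing.assert_allclose(z[f], v, atol=1e-5)

    def test_one_hot_alpha_selects_a_cell(self, rng):
        U = rng.normal(size=(3, 4, 6)).astype(np.float32)
        alpha = np.zeros((1, 3, 4), np.float32)
        alpha[0, 2, 1] = 1.0
        np.testing.assert_allclose(attend(U, alpha), U[2, 1], atol=1e-6)

    def test_matches_nested_loop_oracle(self, rng):
        U = rng.normal(size=(4, 5, 8)).astype(np.float32)
        alpha = normalize_attention(rng.normal(size=(3, 4, 5)).astype(np.float32)).alpha
        assert np.abs(attend(U, alpha) - brute_force_attend(U, alpha)).max() <= 1e-6

    def test_convex_hull_bounds(self, rng):
        """Each head's context vector lies within per-component cell bounds."""
        U = rng.normal(size=(3, 3, 7)).astype(np.float32)
        alpha = normalize_attention(rng.normal(size=(5, 3, 3)).astype(np.float32)).alpha
        z = attend(U, alpha).reshape(5, 7)
        lo = U.reshape(-1, 7).min(axis=0) - 1e-5
        hi = U.reshape(-1, 7).max(axis=0) + 1e-5
        assert ((z >= lo) & (z <= hi)).all()


class TestClassify:
    def test_eval_deterministic_and_sums_to_one(self, rng):
        z = rng.normal(size=12).astype(np.float32)
        W = rng.normal(size=(4, 12)).astype(np.float32)
        b = np.zeros(4, np.float32)
        p1, _ = classify(z, W, b, mode="eval")
        p2, _ = classify(z, W, b, mode="eval")
        np.testing.assert_array_equal(p1, p2)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_dropout_matches_eval(self, rng):
        z = rng.normal(size=12).astype(np.float32)
        W = rng.normal(size=(4, 12)).astype(np.float32)
        b = rng.normal(size=4).astype(np.float32)
        p_train, _ = classify(z, W, b, dropout_p=0.0, mode="train")
        p_eval, _ = classify(z, W, b, mode="eval")
        np.testing.assert_allclose(p_train, p_eval, atol=1e-6)


class TestTransposeEquivariance:
    def test_symmetric_kernels_transpose_with_the_grid(self, rng):
        """Transposing U transposes alpha and leaves z unchanged when the
        spatial kernels are symmetric under transposition."""
        r, c, k, F = 3, 5, 6, 2
        U = rng.normal(size=(r, c, k)).astype(np.float32)
        W = rng.normal(size=(F, k, 3, 3)).astype(np.float32)
        W = 0.5 * (W + W.transpose(0, 1, 3, 2))  # symmetrize spatially
        b = np.zeros(F, np.float32)
        a1 = normalize_attention(compute_attention_logits(U, W, b)).alpha
        a2 = normalize_attention(
            compute_attention_logits(U.transpose(1, 0, 2), W, b)).alpha
        np.testing.assert_allclose(a2, a1.transpose(0, 2, 1), atol=1e-5)
        z1 = attend(U, a1)
        z2 = attend(U.transpose(1, 0, 2), a2)
        np.testing.assert_allclose(z1, z2, atol=1e-5)


class TestModelForward:
    def test_flexible_grid_sizes_one_model_instance(self):
        model = AttentionModel(backbone=make_backbone("tiny", feature_dim=8),
                               config=AttentionConfig(n_filters=3), seed=0)
        dims = set()
        for r, c in [(2, 3), (4, 4)]:
            probs, amap = model.forward(structured_cells(r * c), GridShape(r, c))
            assert amap.alpha.shape == (3, r, c)
            dims.add(probs.shape)
        assert dims == {(4,)}

    def test_eval_forward_deterministic(self, tiny_model):
        cells = structured_cells(6)
        p1, a1 = tiny_model.forward(cells, GridShape(2, 3))
        p2, a2 = tiny_model.forward(cells, GridShape(2, 3))
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(a1.alpha, a2.alpha)

    def test_probabilities_sum_to_one(self, tiny_model):
        probs, _ = tiny_model.forward(structured_cells(6), GridShape(2, 3))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_attention_filter_gradient_matches_finite_difference(self, tiny_model):
        """End-to-end differentiability: nonzero attention gradients that
        agree with central differences of the cross-entropy loss."""
        model = tiny_model
        cells = structured_cells(6)
        grid = GridShape(2, 3)

        def loss_of():
            U = extract_features(cells, model.backbone, grid)
            _, cl, _ = model.forward_features(U)
            return cross_entropy(cl, 2)[0]

        U = extract_features(cells, model.backbone, grid)
        _, cl, _ = model.forward_features(U)
        for p in model.params():
            p.grad[...] = 0
        model.backward(cl, 2)
        g = model.att_conv.weight.grad
        assert np.abs(g).max() > 0
        idx = np.unravel_index(np.abs(g).argmax(), g.shape)
        eps = 1e-2
        w = model.att_conv.weight
        w0 = w.value[idx]
        w.value[idx] = w0 + eps
        lp = loss_of()
        w.value[idx] = w0 - eps
        lm = loss_of()
        w.value[idx] = w0
        assert (lp - lm) / (2 * eps) == pytest.approx(float(g[idx]), rel=0.05, abs=1e-6)

    def test_checkpoint_roundtrip(self, tiny_model, tmp_path):
        cells = structured_cells(6)
        p1, _ = tiny_model.forward(cells, GridShape(2, 3))
        tiny_model.save(tmp_path / "model.npz")
        reloaded = AttentionModel.load(tmp_path / "model.npz")
        p2, _ = reloaded.forward(cells, GridShape(2, 3))
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestAttentionMapInvariants:
    def test_negative_weights_rejected(self):
        bad = np.full((1, 2, 2), 0.25, np.float32)
        bad[0, 0, 0] = -0.25
        bad[0, 1, 1] = 0.75
        with pytest.raises(ValueError, match="nonnegative"):
            AttentionMap(alpha=bad)

    def test_unnormalized_head_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AttentionMap(alpha=np.full((1, 2, 2), 0.3, np.float32))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            AttentionConfig(kernel=4)
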