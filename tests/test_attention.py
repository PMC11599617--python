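"""Attention operations against independent scalar brute-force oracles."""

import math

import numpy as np
import pytest

from vitfusion.attention import (AttentionProjection, AttentionStack,
                                 EncoderBlock, cross_attention,
                                 multi_head_cross_attention,
                                 multi_head_self_attention, self_attention)
from vitfusion.autodiff import Tensor


def scalar_attention(x_rows, y_rows, wq, wk, wv, d_k):
    """Pure-python evaluation of scaled dot-product attention, no numpy."""
    def matvec(rows, w):
        return [[sum(r[i] * w[i][j] for i in range(len(w)))
                 for j in range(len(w[0]))] for r in rows]

    q, k, v = matvec(x_rows, wq), matvec(y_rows, wk), matvec(y_rows, wv)
    out_rows, score_rows = [], []
    for qi in q:
        logits = [sum(a * b for a, b in zip(qi, kj)) / math.sqrt(d_k)
                  for kj in k]
        mx = max(logits)
        exps = [math.exp(l - mx) for l in logits]
        z = sum(exps)
        probs = [e / z for e in exps]
        score_rows.append(probs)
        out_rows.append([sum(p * vj[c] for p, vj in zip(probs, v))
                         for c in range(len(v[0]))])
    return out_rows, score_rows


def project(proj):
    return (proj.w_q.weight.data.tolist(), proj.w_k.weight.data.tolist(),
            proj.w_v.weight.data.tolist())


class TestSelfAttention:
    def test_single_token_scores_collapse_to_one(self, rng):
        proj = AttentionProjection(3, rng)
        x = rng.standard_normal((1, 3))
        out, scores = self_attention(x, proj)
        np.testing.assert_allclose(scores.data, [[1.0]])
        np.testing.assert_allclose(out.data, x @ proj.w_v.weight.data)

    def test_zero_query_weights_give_uniform_scores(self, rng):
        proj = AttentionProjection(3, rng)
        proj.w_q.weight.data[:] = 0
        x = rng.standard_normal((5, 3))
        out, scores = self_attention(x, proj)
        np.testing.assert_allclose(scores.data, 1 / 5, atol=1e-12)
        v = x @ proj.w_v.weight.data
        np.testing.assert_allclose(out.data, np.tile(v.mean(axis=0), (5, 1)))

    def test_matches_scalar_oracle(self, rng):
        proj = AttentionProjection(2, rng)
        x = rng.standard_normal((2, 2))
        out, scores = self_attention(x, proj)
        wq, wk, wv = project(proj)
        o_out, o_scores = scalar_attention(x.tolist(), x.tolist(), wq, wk, wv,
                                           d_k=2)
        np.testing.assert_allclose(out.data, o_out, atol=1e-6)
        np.testing.assert_allclose(scores.data, o_scores, atol=1e-6)

    def test_mismatched_qk_width_rejected(self, rng):
        with pytest.raises(ValueError, match="divide"):
            AttentionProjection(4, rng, heads=3)


class TestMultiHead:
    def test_single_head_identity_output_map_equals_plain(self, rng):
        proj = AttentionProjection(4, rng, heads=1)
        proj.w_out.weight.data = np.eye(4)
        x = rng.standard_normal((3, 4))
        mh_out, head_scores = multi_head_self_attention(x, proj)
        sa_out, sa_scores = self_attention(x, proj)
        np.testing.assert_array_equal(mh_out.data, sa_out.data)
        np.testing.assert_array_equal(head_scores[0], sa_scores.data)

    def test_head_permutation_with_permuted_output_rows(self, rng):
        proj = AttentionProjection(4, rng, heads=2)
        x = rng.standard_normal((3, 4))
        base, _ = multi_head_self_attention(x, proj)
        swapped = AttentionProjection(4, rng, heads=2)
        for name in ("w_q", "w_k", "w_v"):
            w = getattr(proj, name).weight.data
            getattr(swapped, name).weight.data = np.concatenate(
                [w[:, 2:], w[:, :2]], axis=1)
        wo = proj.w_out.weight.data
        swapped.w_out.weight.data = np.concatenate([wo[2:], wo[:2]], axis=0)
        out2, _ = multi_head_self_attention(x, swapped)
        np.testing.assert_allclose(out2.data, base.data, atol=1e-12)

    def test_two_heads_match_per_head_oracle(self, rng):
        proj = AttentionProjection(4, rng, heads=2)
        x = rng.standard_normal((3, 4))
        out, head_scores = multi_head_self_attention(x, proj)
        heads = []
        for i in range(2):
            wq = proj.w_q.weight.data[:, 2 * i:2 * i + 2].tolist()
            wk = proj.w_k.weight.data[:, 2 * i:2 * i + 2].tolist()
            wv = proj.w_v.weight.data[:, 2 * i:2 * i + 2].tolist()
            o, s = scalar_attention(x.tolist(), x.tolist(), wq, wk, wv, d_k=2)
            heads.append(np.asarray(o))
            np.testing.assert_allclose(head_scores[i], s, atol=1e-6)
        oracle = np.concatenate(heads, axis=1) @ proj.w_out.weight.data
        np.testing.assert_allclose(out.data, oracle, atol=1e-6)


class TestCrossAttention:
    def test_self_degenerate_case(self, rng):
        proj = AttentionProjection(3, rng)
        x = rng.standard_normal((4, 3))
        ca_out, ca_scores = cross_attention(x, x, proj)
        sa_out, sa_scores = self_attention(x, proj)
        np.testing.assert_array_equal(ca_out.data, sa_out.data)
        np.testing.assert_array_equal(ca_scores.data, sa_scores.data)

    def test_single_key_gets_all_attention(self, rng):
        proj = AttentionProjection(3, rng)
        x = rng.standard_normal((4, 3))
        y = rng.standard_normal((1, 3))
        out, scores = cross_attention(x, y, proj)
        np.testing.assert_allclose(scores.data, 1.0)
        np.testing.assert_allclose(out.data,
                                   np.tile(y @ proj.w_v.weight.data, (4, 1)))

    def test_matches_scalar_oracle_n2_m3(self, rng):
        proj = AttentionProjection(2, rng)
        x = rng.standard_normal((2, 2))
        y = rng.standard_normal((3, 2))
        out, scores = cross_attention(x, y, proj)
        wq, wk, wv = project(proj)
        o_out, o_scores = scalar_attention(x.tolist(), y.tolist(), wq, wk, wv,
                                           d_k=2)
        assert scores.shape == (2, 3)
        np.testing.assert_allclose(out.data, o_out, atol=1e-6)
        np.testing.assert_allclose(scores.data, o_scores, atol=1e-6)

    def test_constant_values_make_scores_irrelevant(self, rng):
        proj = AttentionProjection(3, rng, heads=1)
        proj.w_out.weight.data = np.eye(3)
        x = rng.standard_normal((4, 3))
        y = np.tile(rng.standard_normal(3), (2, 1))
        out, _ = multi_head_cross_attention(x, y, proj)
        np.testing.assert_allclose(out.data - out.data[0], 0, atol=1e-12)

    def test_multi_head_cross_matches_per_head_oracle(self, rng):
        proj = AttentionProjection(4, rng, heads=2)
        x = rng.standard_normal((2, 4))
        y = rng.standard_normal((3, 4))
        out, head_scores = multi_head_cross_attention(x, y, proj)
        heads = []
        for i in range(2):
            wq = proj.w_q.weight.data[:, 2 * i:2 * i + 2].tolist()
            wk = proj.w_k.weight.data[:, 2 * i:2 * i + 2].tolist()
            wv = proj.w_v.weight.data[:, 2 * i:2 * i + 2].tolist()
            o, s = scalar_attention(x.tolist(), y.tolist(), wq, wk, wv, d_k=2)
            heads.append(np.asarray(o))
            np.testing.assert_allclose(head_scores[i], s, atol=1e-6)
        oracle = np.concatenate(heads, axis=1) @ proj.w_out.weight.data
        np.testing.assert_allclose(out.data, oracle, atol=1e-6)

    def test_width_mismatch_rejected(self, rng):
        proj = AttentionProjection(3, rng)
        with pytest.raises(ValueError, match="d_model"):
            cross_attention(np.zeros((2, 4)), np.zeros((2, 3)), proj)


class TestProperties:
    def test_rows_stochastic_for_any_input(self, rng):
        proj = AttentionProjection(6, rng, heads=3)
        for scale in (1e-3, 1.0, 1e3):
            x = scale * rng.standard_normal((2, 7, 6))
            _, head_scores = multi_head_self_attention(x, proj)
            for s in head_scores:
                assert np.all(s >= 0)
                np.testing.assert_allclose(s.sum(axis=-1), 1.0, atol=1e-6)

    def test_uniform_logit_scaling_acts_as_temperature(self, rng):
        proj = AttentionProjection(2, rng)
        x = rng.standard_normal((3, 2))
        c = 2.0
        hot = AttentionProjection(2, rng)
        hot.w_q.weight.data = proj.w_q.weight.data * c
        hot.w_k.weight.data = proj.w_k.weight.data * c
        hot.w_v.weight.data = proj.w_v.weight.data
        _, scores = self_attention(x, proj)
        _, scores_hot = self_attention(x, hot)
        q = x @ proj.w_q.weight.data
        k = x @ proj.w_k.weight.data
        logits = q @ k.T / np.sqrt(2)
        exp = np.exp(c * c * logits - (c * c * logits).max(1, keepdims=True))
        np.testing.assert_allclose(scores_hot.data,
                                   exp / exp.sum(1, keepdims=True), atol=1e-12)
        assert not np.allclose(scores.data, scores_hot.data)


class TestEncoderBlock:
    def test_zero_sublayer_weights_give_identity(self, rng):
        block = EncoderBlock(4, heads=2, rng=rng)
        block.attn.w_v.weight.data[:] = 0
        block.attn.w_out.weight.data[:] = 0
        for lin in (block.mlp.fc1, block.mlp.fc2):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        x = rng.standard_normal((2, 5, 4))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-12)

    def test_output_shape_preserved(self, rng, tiny_model):
        block = EncoderBlock(8, heads=2, rng=rng)
        x = Tensor(rng.standard_normal((3, 6, 8)))
        assert block(x).shape == (3, 6, 8)

    def test_matches_composed_sublayer_oracle(self, rng):
        block = EncoderBlock(6, heads=2, rng=rng)
        x = Tensor(rng.standard_normal((2, 4, 6)))
        out = block(x)
        attn_out, _ = multi_head_self_attention(block.norm1(x), block.attn)
        x1 = x + attn_out
        oracle = x1 + block.mlp(block.norm2(x1))
        np.testing.assert_allclose(out.data, oracle.data, atol=1e-12)

    def test_capture_does_not_alter_output(self, rng):
        block = EncoderBlock(4, heads=2, rng=rng)
        x = Tensor(rng.standard_normal((2, 3, 4)))
        stack = AttentionStack()
        with_capture = block(x, capture=stack)
        without = block(x)
        np.testing.assert_array_equal(with_capture.data, without.data)
        assert stack.n_layers == 1 and stack.n_heads == 2
        stack.validate()
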