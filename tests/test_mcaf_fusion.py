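"""Gated multi-head cross-channel attention fusion."""

import numpy as np
import pytest

from mcafnet.autodiff import Tensor
from mcafnet.mcaf_fusion import (AttentionParams, cross_channel_attention,
                                 dynamic_gate, fuse_layer, fuse_stack,
                                 merge_heads_project, project_qkv)


def brute_force_attention(qd, kd, vd):
    """Six-nested-loop scalar reference of the cross-channel attention."""
    b, c, length, h, dh = qd.shape
    out = np.zeros((b, c, length, h * dh))
    for bb in range(b):
        for hh in range(h):
            for i in range(c):
                acc = np.zeros((length, dh))
                for j in range(c):
                    scores = np.empty((length, length))
                    for lq in range(length):
                        for lk in range(length):
                            scores[lq, lk] = (
                                qd[bb, i, lq, hh] @ kd[bb, j, lk, hh]
                                / np.sqrt(dh))
                    w = np.exp(scores - scores.max(axis=1, keepdims=True))
                    w /= w.sum(axis=1, keepdims=True)
                    acc += w @ vd[bb, j, :, hh, :]
                out[bb, i, :, hh * dh:(hh + 1) * dh] = acc
    return out


class TestProjectQkv:
    def test_shapes(self, rng):
        p = AttentionParams(d=128, heads=4, rng=rng)
        q, k, v = project_qkv(Tensor(rng.normal(size=(1, 3, 29, 128))), p)
        for t in (q, k, v):
            assert t.shape == (1, 3, 29, 4, 32)

    def test_zero_weights_give_zero_qkv(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        p.qkv_weight.data[:] = 0
        p.qkv_bias.data[:] = 0
        q, k, v = project_qkv(Tensor(rng.normal(size=(1, 2, 3, 8))), p)
        for t in (q, k, v):
            assert np.allclose(t.data, 0.0)

    def test_identity_blocks_reproduce_input(self, rng):
        d = 6
        p = AttentionParams(d=d, heads=2, rng=rng)
        p.qkv_weight.data = np.hstack([np.eye(d)] * 3)
        p.qkv_bias.data[:] = 0
        x = rng.normal(size=(2, 2, 3, d))
        q, k, v = project_qkv(Tensor(x), p)
        for t in (q, k, v):
            assert np.allclose(t.data.reshape(2, 2, 3, d), x)

    def test_dim_mismatch_rejected(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        with pytest.raises(ValueError):
            project_qkv(Tensor(np.zeros((1, 2, 3, 6))), p)


class TestCrossChannelAttention:
    def test_single_channel_reduces_to_self_attention(self, rng):
        # C=1 must equal textbook multi-head self-attention
        q = rng.normal(size=(2, 1, 4, 2, 3))
        k = rng.normal(size=(2, 1, 4, 2, 3))
        v = rng.normal(size=(2, 1, 4, 2, 3))
        out, _ = cross_channel_attention(Tensor(q), Tensor(k), Tensor(v))
        ref = np.zeros((2, 1, 4, 6))
        for bb in range(2):
            for hh in range(2):
                scores = q[bb, 0, :, hh] @ k[bb, 0, :, hh].T / np.sqrt(3)
                w = np.exp(scores - scores.max(axis=1, keepdims=True))
                w /= w.sum(axis=1, keepdims=True)
                ref[bb, 0, :, hh * 3:(hh + 1) * 3] = w @ v[bb, 0, :, hh]
        assert np.abs(out.data - ref).max() < 1e-10

    def test_constant_keys_give_uniform_weights(self, rng):
        b, c, length, h, dh = 1, 2, 5, 2, 3
        q = rng.normal(size=(b, c, length, h, dh))
        k = np.broadcast_to(rng.normal(size=(b, c, 1, h, dh)),
                            (b, c, length, h, dh)).copy()
        v = rng.normal(size=(b, c, length, h, dh))
        out, maps = cross_channel_attention(Tensor(q), Tensor(k), Tensor(v))
        assert np.allclose(maps.weights, 1.0 / length)
        expect = v.mean(axis=2).sum(axis=1)        # sum_j mean_l V_j [B,H,dh]
        for i in range(c):
            got = out.data[:, i].reshape(b, length, h, dh)
            assert np.allclose(got, expect[:, None], atol=1e-12)

    def test_matches_brute_force_over_shape_grid(self, rng):
        for b in (1, 2):
            for c in (1, 2, 3):
                for length in (1, 2, 4):
                    for h in (1, 2):
                        q = rng.normal(size=(b, c, length, h, 4 // h))
                        k = rng.normal(size=q.shape)
                        v = rng.normal(size=q.shape)
                        out, _ = cross_channel_attention(
                            Tensor(q), Tensor(k), Tensor(v))
                        ref = brute_force_attention(q, k, v)
                        assert np.abs(out.data - ref).max() < 1e-6

    def test_weights_normalized_and_total_mass_is_c(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        x = rng.normal(size=(2, 3, 5, 8))
        _, maps = fuse_layer(Tensor(x), p)
        w = maps.weights
        assert (w >= 0).all() and (w <= 1).all()
        assert np.abs(w.sum(axis=-1) - 1).max() < 1e-5
        # each query position receives one unit per key channel -> C total
        mass = w.sum(axis=(3, 5))  # sum over key channel and key position
        assert np.allclose(mass, 3.0, atol=1e-4)

    def test_nonfinite_scores_rejected(self):
        bad = np.full((1, 1, 2, 1, 2), 1e300)
        with pytest.raises(FloatingPointError):
            cross_channel_attention(Tensor(bad), Tensor(bad),
                                    Tensor(np.ones_like(bad)))


class TestMergeHeadsProject:
    def test_identity_and_zero(self, rng):
        p = AttentionParams(d=4, heads=2, rng=rng)
        o = Tensor(rng.normal(size=(1, 2, 3, 4)))
        p.out_weight.data = np.eye(4)
        p.out_bias.data[:] = 0
        assert np.allclose(merge_heads_project(o, p).data, o.data)
        p.out_weight.data[:] = 0
        assert np.allclose(merge_heads_project(o, p).data, 0.0)

    def test_matches_explicit_matmul(self, rng):
        p = AttentionParams(d=4, heads=2, rng=rng)
        o = rng.normal(size=(2, 3, 5, 4))
        got = merge_heads_project(Tensor(o), p).data
        expect = o @ p.out_weight.data + p.out_bias.data
        assert np.allclose(got, expect)


class TestDynamicGate:
    def test_zero_parameters_give_half(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        g = dynamic_gate(Tensor(rng.normal(size=(3, 2, 4, 8))), p)
        assert np.allclose(g.data, 0.5)

    def test_large_negative_bias_closes_gate(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        p.gate_bias.data[:] = -20.0
        g = dynamic_gate(Tensor(rng.normal(size=(2, 2, 4, 8))), p)
        assert np.allclose(g.data, 1.0 / (1.0 + np.exp(20.0)), rtol=1e-6)

    def test_constant_input_closed_form(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        p.gate_weight.data = rng.normal(size=(8, 1))
        p.gate_bias.data[:] = 0.3
        c = 1.7
        g = dynamic_gate(Tensor(np.full((1, 3, 4, 8), c)), p)
        expect = 1.0 / (1.0 + np.exp(-(c * p.gate_weight.data.sum() + 0.3)))
        assert np.allclose(g.data, expect)

    def test_gate_strictly_inside_unit_interval(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        p.gate_weight.data = rng.normal(size=(8, 1))
        g = dynamic_gate(Tensor(rng.normal(size=(16, 3, 4, 8)) * 5), p)
        assert ((g.data > 0) & (g.data < 1)).all()


class TestFuseLayer:
    def test_closed_gate_residual_identity(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        p.gate_bias.data[:] = -1e3
        x = rng.normal(size=(2, 3, 5, 8))
        y, _ = fuse_layer(Tensor(x), p)
        assert np.abs(y.data - x).max() < 1e-6

    def test_zero_projection_exact_identity(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        p.out_weight.data[:] = 0
        p.out_bias.data[:] = 0
        x = rng.normal(size=(1, 3, 4, 8))
        y, _ = fuse_layer(Tensor(x), p)
        assert np.array_equal(y.data, x)

    def test_equals_composition_of_sub_operations(self, rng):
        p = AttentionParams(d=4, heads=2, rng=rng)
        p.gate_weight.data = rng.normal(size=(4, 1))
        x = rng.normal(size=(2, 2, 3, 4))
        y, _ = fuse_layer(Tensor(x), p)
        q, k, v = project_qkv(Tensor(x), p)
        ref_o = brute_force_attention(q.data, k.data, v.data)
        ref_oproj = ref_o @ p.out_weight.data + p.out_bias.data
        xm = x.mean(axis=(1, 2))
        g = 1.0 / (1.0 + np.exp(-(xm @ p.gate_weight.data
                                  + p.gate_bias.data)))
        ref_y = x + g[:, :, None, None] * ref_oproj
        assert np.abs(y.data - ref_y).max() < 1e-10

    def test_channel_permutation_equivariance(self, rng):
        p = AttentionParams(d=8, heads=2, rng=rng)
        p.gate_weight.data = rng.normal(size=(8, 1))
        x = rng.normal(size=(2, 3, 5, 8))
        perm = [2, 0, 1]
        y, _ = fuse_layer(Tensor(x), p)
        y_perm, _ = fuse_layer(Tensor(x[:, perm]), p)
        assert np.allclose(y_perm.data, y.data[:, perm], atol=1e-12)


class TestFuseStack:
    def test_single_layer_equals_fuse_layer(self, rng):
        p = AttentionParams(d=4, heads=2, rng=rng)
        x = rng.normal(size=(1, 2, 3, 4))
        y1, _ = fuse_layer(Tensor(x), p)
        y2, maps = fuse_stack(Tensor(x), [p])
        assert np.array_equal(y1.data, y2.data)
        assert len(maps) == 1

    def test_two_closed_gates_identity_chain(self, rng):
        ps = [AttentionParams(d=4, heads=2, rng=rng) for _ in range(2)]
        for p in ps:
            p.gate_bias.data[:] = -1e3
        x = rng.normal(size=(1, 3, 4, 4))
        y, _ = fuse_stack(Tensor(x), ps)
        assert np.abs(y.data - x).max() < 1e-6

    def test_two_layers_equal_manual_composition(self, rng):
        ps = [AttentionParams(d=4, heads=2, rng=rng) for _ in range(2)]
        x = rng.normal(size=(2, 2, 3, 4))
        y_stack, maps = fuse_stack(Tensor(x), ps)
        mid, _ = fuse_layer(Tensor(x), ps[0])
        end, _ = fuse_layer(mid, ps[1])
        assert np.array_equal(y_stack.data, end.data)
        assert [m.layer_index for m in maps] == [0, 1]

    def test_empty_stack_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse_stack(Tensor(np.zeros((1, 2, 3, 4))), [])


def test_indivisible_head_count_rejected():
    with pytest.raises(ValueError):
        AttentionParams(d=6, heads=4)
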