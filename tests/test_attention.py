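"""Window attention and LeFF against independent loop-based oracles."""

import numpy as np
import pytest

from cbct2ct import autodiff as ad
from cbct2ct.autodiff import Tensor
from cbct2ct.transformer import (AttentionConfig, LeFF, TransformerBlock,
                                 WindowAttention)
from cbct2ct.windows import (build_attention_mask, cyclic_shift,
                             cyclic_unshift, merge_windows,
                             partition_windows)


def brute_force_attention(wa: WindowAttention, w: np.ndarray,
                          mask: np.ndarray | None = None) -> np.ndarray:
    """Explicit loops over windows, heads and token pairs (float64)."""
    cfg = wa.cfg
    B, T, C = w.shape
    k, d = cfg.n_heads, cfg.head_dim
    Wq, bq = wa.q.weight.data, wa.q.bias.data
    Wk, bk = wa.k.weight.data, wa.k.bias.data
    Wv, bv = wa.v.weight.data, wa.v.bias.data
    Wo, bo = wa.proj.weight.data, wa.proj.bias.data
    tbl, idx = wa.bias_table.data, wa.rel_index
    scale = 1 / np.sqrt(d) if cfg.scale_by_sqrt_d else 1 / d
    out = np.zeros((B, T, C))
    for b in range(B):
        q = w[b] @ Wq + bq
        kk = w[b] @ Wk + bk
        v = w[b] @ Wv + bv
        heads = []
        for h in range(k):
            sl = slice(h * d, (h + 1) * d)
            logits = np.zeros((T, T))
            for i in range(T):
                for j in range(T):
                    logits[i, j] = q[i, sl] @ kk[j, sl] * scale \
                        + tbl[idx[i, j], h]
                    if mask is not None:
                        logits[i, j] += mask[b % mask.shape[0], i, j]
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            a = e / e.sum(axis=1, keepdims=True)
            heads.append(a @ v[:, sl])
        out[b] = np.concatenate(heads, axis=1) @ Wo + bo
    return out


def full_attention_path(wa, x, s, M, H, W):
    xs = cyclic_shift(x, s)
    w = partition_windows(xs, M)
    mask = build_attention_mask(H, W, M, s) if s > 0 else None
    y = wa(w, mask)
    return cyclic_unshift(merge_windows(y, H, W), s), w, mask


@pytest.mark.parametrize("k", [1, 2])
@pytest.mark.parametrize("shift", [0, 2])
def test_attention_matches_brute_force(k, shift, rng):
    """Full windowed/shifted attention path equals the loop oracle (8x8)."""
    M, C, H = 4, 4, 8
    cfg = AttentionConfig(window_size=M, n_heads=k, channels=C, shift=shift)
    wa = WindowAttention(cfg, rng)
    x = Tensor(rng.standard_normal((1, C, H, H)).astype(np.float32))
    y, w, mask = full_attention_path(wa, x, shift, M, H, H)
    oracle = brute_force_attention(wa, w.data.astype(np.float64), mask)
    oracle_map = cyclic_unshift(
        merge_windows(Tensor(oracle.astype(np.float32)), H, H), shift)
    scale = np.abs(oracle_map.data).max()
    assert np.abs(y.data - oracle_map.data).max() / scale < 1e-5


def test_attention_rows_sum_to_one(rng):
    cfg = AttentionConfig(window_size=4, n_heads=2, channels=8, shift=2)
    wa = WindowAttention(cfg, rng)
    x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
    xs = cyclic_shift(x, 2)
    w = partition_windows(xs, 4)
    mask = build_attention_mask(8, 8, 4, 2)
    _, attn = wa(w, mask, return_weights=True)
    assert np.all(attn.data >= 0)
    np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)


def test_single_token_window_ignores_bias(rng):
    """M=1: softmax over one key is 1, so output = proj(V) whatever B is."""
    cfg = AttentionConfig(window_size=1, n_heads=1, channels=3)
    wa = WindowAttention(cfg, rng)
    wa.bias_table.data[:] = 123.0        # must not matter
    w = Tensor(rng.standard_normal((5, 1, 3)).astype(np.float32))
    y = wa(w)
    v = w.data @ wa.v.weight.data + wa.v.bias.data
    want = v @ wa.proj.weight.data + wa.proj.bias.data
    np.testing.assert_allclose(y.data, want, rtol=1e-5, atol=1e-6)


def test_identical_keys_give_uniform_weights(rng):
    """Zero bias + constant K rows -> every token averages the V rows."""
    cfg = AttentionConfig(window_size=2, n_heads=1, channels=2)
    wa = WindowAttention(cfg, rng)
    wa.bias_table.data[:] = 0.0
    wa.k.weight.data[:] = 0.0            # K rows all equal the K bias
    w = Tensor(rng.standard_normal((1, 4, 2)).astype(np.float32))
    _, attn = wa(w, None, return_weights=True)
    np.testing.assert_allclose(attn.data, 0.25, atol=1e-6)


def test_translation_by_window_equivariance(rng):
    """Shifting input by exactly M pixels permutes windows only, so
    unshifted window attention commutes with the translation."""
    M, C, H = 4, 4, 8
    cfg = AttentionConfig(window_size=M, n_heads=2, channels=C, shift=0)
    wa = WindowAttention(cfg, rng)
    x = Tensor(rng.standard_normal((1, C, H, H)).astype(np.float32))

    def apply(xx):
        return merge_windows(wa(partition_windows(xx, M)), H, H)

    y = apply(x)
    y_shifted = apply(cyclic_shift(x, M))
    np.testing.assert_allclose(cyclic_unshift(y_shifted, M).data, y.data,
                               rtol=1e-5, atol=1e-6)


class TestLeFF:
    def test_shape_contract(self, rng):
        leff = LeFF(6, 2, rng)
        t = Tensor(rng.standard_normal((2, 16, 6)).astype(np.float32))
        assert leff(t, 4, 4).shape == (2, 16, 6)

    def test_identity_linears_reduce_to_gelu_chain(self, rng):
        """With identity linears and an identity depthwise kernel the layer
        is the pointwise triple-GELU, checked by hand on a 2x2 map."""
        from scipy.special import erf

        leff = LeFF(2, 1, rng)
        leff.expand.weight.data = np.eye(2, dtype=np.float32)
        leff.expand.bias.data[:] = 0
        leff.shrink.weight.data = np.eye(2, dtype=np.float32)
        leff.shrink.bias.data[:] = 0
        leff.dw.weight.data[:] = 0
        leff.dw.weight.data[:, 1, 1] = 1.0   # identity 3x3 kernel
        leff.dw.bias.data[:] = 0
        t0 = np.array([[[0.5, -0.3], [1.0, 0.2], [-1.5, 0.0], [2.0, -0.7]]],
                      dtype=np.float32)

        def g(v):
            return 0.5 * v * (1 + erf(v / np.sqrt(2)))

        want = g(g(g(t0.astype(np.float64))))
        out = leff(Tensor(t0), 2, 2)
        np.testing.assert_allclose(out.data, want, rtol=1e-5, atol=1e-6)

    def test_depthwise_locality(self, rng):
        """A single changed pixel can only alter the 3x3 neighborhood at
        the depthwise stage (here: whole output since maps are tiny, so
        probe on a 6x6 map instead)."""
        leff = LeFF(3, 2, rng)
        H = W = 6
        t0 = rng.standard_normal((1, H * W, 3)).astype(np.float32)
        base = leff(Tensor(t0), H, W).data
        t1 = t0.copy()
        t1[0, 0, :] += 1.0                   # perturb pixel (0, 0)
        out = leff(Tensor(t1), H, W).data
        changed = np.any(out != base, axis=(0, 2)).reshape(H, W)
        rows, cols = np.where(changed)
        assert rows.max() <= 1 and cols.max() <= 1


class TestTransformerBlock:
    def test_zeroed_branches_make_identity(self, rng):
        cfg = AttentionConfig(window_size=4, n_heads=2, channels=4, shift=0)
        blk = TransformerBlock(cfg, 2, rng)
        blk.attn.proj.weight.data[:] = 0
        blk.attn.proj.bias.data[:] = 0
        blk.leff.shrink.weight.data[:] = 0
        blk.leff.shrink.bias.data[:] = -10.0  # GELU(-10) ~ 0 exactly enough
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(blk(x).data, x.data, atol=1e-6)

    def test_output_shape_always_input_shape(self, rng):
        for shift in (0, 2):
            cfg = AttentionConfig(window_size=4, n_heads=1, channels=4,
                                  shift=shift)
            blk = TransformerBlock(cfg, 2, rng)
            x = Tensor(rng.standard_normal((2, 4, 8, 12)).astype(np.float32))
            assert blk(x).shape == x.shape

    def test_unshifted_block_matches_manual_composition(self, rng):
        """Block output equals norm->window attention->residual->norm->LeFF
        composed by hand on an 8x8, C=4 map."""
        cfg = AttentionConfig(window_size=4, n_heads=2, channels=4, shift=0)
        blk = TransformerBlock(cfg, 2, rng)
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        got = blk(x)

        from cbct2ct.windows import img_to_tokens, tokens_to_img
        t = img_to_tokens(x)
        n1 = blk.norm1(t)
        w = partition_windows(tokens_to_img(n1, 8, 8), 4)
        a_oracle = brute_force_attention(blk.attn,
                                         w.data.astype(np.float64))
        mid = x.data + merge_windows(
            Tensor(a_oracle.astype(np.float32)), 8, 8).data
        t2 = img_to_tokens(Tensor(mid))
        n2 = blk.norm2(t2)
        leff_out = blk.leff(n2, 8, 8)
        want = mid + tokens_to_img(leff_out, 8, 8).data
        np.testing.assert_allclose(got.data, want, rtol=1e-4, atol=1e-5)
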