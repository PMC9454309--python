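"""U-shaped hierarchical encoder-decoder with shifted-window self-attention.

The network translates a single-channel normalized CBCT slice into the
corresponding CT slice.  Shallow features come from a 3x3 convolution with
LeakyReLU; four encoder stages of two transformer blocks each (window
attention then shifted-window attention) alternate with 4x4 stride-2
convolutional downsamplers; a two-block bottleneck sits at 16x the base
channel width; four decoder stages mirror the encoder with 2x2 stride-2
transposed-convolution upsamplers and concatenation skip connections; a 3x3
convolution projects back to one channel.

Each block computes

    x <- x + W-MSA(LN(x));   x <- x + LeFF(LN(x))

where the multi-head attention within every M x M window is

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d) + B [+ mask]) V

with per-head dimension d = C/k and a learned relative position bias B
indexed by the 2D offset between tokens (a (2M-1)^2 x k table shared by all
windows).  The LeFF (locally enhanced feed-forward) layer expands tokens
linearly, applies a 3x3 depth-wise convolution on the re-gridded map, and
shrinks back, with GELU after every linear/convolutional layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .windows import (build_attention_mask, cyclic_shift, cyclic_unshift,
                      img_to_tokens, merge_windows, partition_windows,
                      tokens_to_img)


@dataclass(frozen=True)
class AttentionConfig:
    """Shape parameters of one windowed attention layer."""

    window_size: int          # M, window side length in tokens
    n_heads: int              # k
    channels: int             # C
    shift: int = 0            # cyclic shift offset, 0 <= shift < M
    scale_by_sqrt_d: bool = True  # QK^T / sqrt(d); False uses 1/d as printed

    def __post_init__(self):
        if self.channels % self.n_heads:
            raise ValueError("channels must be divisible by the head count")
        if not 0 <= self.shift < self.window_size:
            raise ValueError("shift must satisfy 0 <= shift < window size")
        if self.window_size < 1:
            raise ValueError("window size must be >= 1")

    @property
    def head_dim(self) -> int:
        return self.channels // self.n_heads


def relative_position_index(M: int) -> np.ndarray:
    """(M^2, M^2) map from token pairs to rows of the (2M-1)^2 bias table.

    Depends only on the 2D offset between the two tokens, so the resulting
    bias matrix is shared across windows.
    """
    coords = np.stack(np.meshgrid(np.arange(M), np.arange(M),
                                  indexing="ij"), axis=0).reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]       # 2, M^2, M^2
    rel = rel + (M - 1)                                 # shift into [0, 2M-2]
    return (rel[0] * (2 * M - 1) + rel[1]).astype(np.int64)


class WindowAttention(nn.Module):
    """Multi-head self-attention within flattened M x M windows."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        C, M = cfg.channels, cfg.window_size
        self.cfg = cfg
        self.q = nn.Linear(C, C, rng)
        self.k = nn.Linear(C, C, rng)
        self.v = nn.Linear(C, C, rng)
        self.proj = nn.Linear(C, C, rng)
        self.bias_table = Tensor(nn.trunc_normal(rng, ((2 * M - 1) ** 2,
                                                       cfg.n_heads)),
                                 requires_grad=True)
        self.rel_index = relative_position_index(M)     # constant, not learned

    def __call__(self, w: Tensor, mask: np.ndarray | None = None,
                 return_weights: bool = False):
        """w: (B, M^2, C) window stack; mask: (n_windows, M^2, M^2) or None."""
        cfg = self.cfg
        B, T, C = w.shape
        k_h, d = cfg.n_heads, cfg.head_dim
        if not np.isfinite(w.data).all():
            raise FloatingPointError("non-finite attention input")

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, k_h, d).transpose(0, 2, 1, 3)  # B,k,T,d

        q, k, v = heads(self.q(w)), heads(self.k(w)), heads(self.v(w))
        scale = (1.0 / np.sqrt(d)) if cfg.scale_by_sqrt_d else (1.0 / d)
        logits = (q @ k.transpose(0, 1, 3, 2)) * scale            # B,k,T,T
        bias = ad.gather_rows(self.bias_table, self.rel_index.reshape(-1))
        bias = bias.reshape(T, T, k_h).transpose(2, 0, 1)          # k,T,T
        logits = logits + bias
        if mask is not None:
            nw = mask.shape[0]
            logits = (logits.reshape(B // nw, nw, k_h, T, T)
                      + mask[None, :, None, :, :]).reshape(B, k_h, T, T)
        attn = ad.softmax(logits, axis=-1)
        out = attn @ v                                             # B,k,T,d
        out = out.transpose(0, 2, 1, 3).reshape(B, T, C)
        out = self.proj(out)
        if return_weights:
            return out, attn
        return out


class LeFF(nn.Module):
    """Locally enhanced feed-forward: expand -> 3x3 depth-wise conv -> shrink."""

    def __init__(self, channels: int, expansion: int,
                 rng: np.random.Generator):
        hidden = channels * expansion
        self.expand = nn.Linear(channels, hidden, rng)
        self.dw = nn.DepthwiseConv3x3(hidden, rng)
        self.shrink = nn.Linear(hidden, channels, rng)

    def __call__(self, tokens: Tensor, H: int, W: int) -> Tensor:
        t = ad.gelu(self.expand(tokens))
        x = ad.gelu(self.dw(tokens_to_img(t, H, W)))
        return ad.gelu(self.shrink(img_to_tokens(x)))


class TransformerBlock(nn.Module):
    """Pre-norm residual block: W-MSA (optionally shifted) then LeFF."""

    def __init__(self, cfg: AttentionConfig, leff_expansion: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.norm1 = nn.LayerNorm(cfg.channels)
        self.attn = WindowAttention(cfg, rng)
        self.norm2 = nn.LayerNorm(cfg.channels)
        self.leff = LeFF(cfg.channels, leff_expansion, rng)
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def _mask(self, H: int, W: int) -> np.ndarray | None:
        s = self.cfg.shift
        if s == 0:
            return None
        key = (H, W)
        if key not in self._mask_cache:
            self._mask_cache[key] = build_attention_mask(
                H, W, self.cfg.window_size, s)
        return self._mask_cache[key]

    def __call__(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        M, s = self.cfg.window_size, self.cfg.shift
        t = img_to_tokens(x)
        a = tokens_to_img(self.norm1(t), H, W)
        a = cyclic_shift(a, s)
        w = partition_windows(a, M)
        w = self.attn(w, self._mask(H, W))
        a = cyclic_unshift(merge_windows(w, H, W), s)
        x = x + a
        t = self.norm2(img_to_tokens(x))
        return x + tokens_to_img(self.leff(t, H, W), H, W)


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the encoder-decoder.

    ``base_channels`` is the shallow-feature width C0; encoder stages run at
    C0 times the per-stage multiplier and the bottleneck at
    ``bottleneck_multiplier`` x C0.  Inputs are reflect-padded to a multiple
    of ``window_size * 2**n_stages`` so every resolution divides the window.
    """

    base_channels: int = 32
    n_stages: int = 4
    blocks_per_stage: int = 2
    channel_multipliers: tuple[int, ...] = (1, 2, 4, 8)
    bottleneck_multiplier: int = 16
    heads: tuple[int, ...] = (1, 2, 4, 8, 16)
    window_size: int = 8
    leff_expansion: int = 4
    leaky_slope: float = 0.01
    scale_by_sqrt_d: bool = True
    global_residual: bool = False

    def __post_init__(self):
        if len(self.channel_multipliers) != self.n_stages:
            raise ValueError("need one channel multiplier per stage")
        if len(self.heads) != self.n_stages + 1:
            raise ValueError("need heads for each stage plus the bottleneck")
        if any(m <= 0 for m in self.channel_multipliers):
            raise ValueError("channel multipliers must be positive")

    @property
    def stage_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * m for m in self.channel_multipliers)

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * self.bottleneck_multiplier

    @property
    def pad_multiple(self) -> int:
        return self.window_size * 2 ** self.n_stages

    def to_dict(self) -> dict:
        return {
            "base_channels": self.base_channels,
            "n_stages": self.n_stages,
            "blocks_per_stage": self.blocks_per_stage,
            "channel_multipliers": list(self.channel_multipliers),
            "bottleneck_multiplier": self.bottleneck_multiplier,
            "heads": list(self.heads),
            "window_size": self.window_size,
            "leff_expansion": self.leff_expansion,
            "leaky_slope": self.leaky_slope,
            "scale_by_sqrt_d": self.scale_by_sqrt_d,
            "global_residual": self.global_residual,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for key in ("channel_multipliers", "heads"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage_blocks(cfg: NetworkConfig, channels: int, heads: int,
                  rng: np.random.Generator) -> list[TransformerBlock]:
    blocks = []
    for b in range(cfg.blocks_per_stage):
        shift = cfg.window_size // 2 if b % 2 == 1 else 0
        acfg = AttentionConfig(window_size=cfg.window_size, n_heads=heads,
                               channels=channels, shift=shift,
                               scale_by_sqrt_d=cfg.scale_by_sqrt_d)
        blocks.append(TransformerBlock(acfg, cfg.leff_expansion, rng))
    return blocks


class SwinTranslator(nn.Module):
    """The full CBCT -> CT image translation network."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = cfg.stage_channels
        cb = cfg.bottleneck_channels
        self.input_proj = nn.Conv2d(1, ch[0], 3, rng, padding=1)
        self.enc_stages = [
            _stage_blocks(cfg, ch[i], cfg.heads[i], rng)
            for i in range(cfg.n_stages)
        ]
        down_out = list(ch[1:]) + [cb]
        self.downs = [
            nn.Conv2d(ch[i], down_out[i], 4, rng, stride=2, padding=1)
            for i in range(cfg.n_stages)
        ]
        self.bottleneck = _stage_blocks(cfg, cb, cfg.heads[-1], rng)
        up_in = [cb] + list(ch[1:][::-1])               # 16C,8C,4C,2C
        self.ups = [
            nn.ConvTranspose2x2(up_in[i], ch[::-1][i], rng)
            for i in range(cfg.n_stages)
        ]
        # skip fusion: concat(up, skip) then 1x1 channel-reducing projection
        self.fuses = [
            nn.Conv2d(2 * c, c, 1, rng) for c in ch[::-1]
        ]
        self.dec_stages = [
            _stage_blocks(cfg, c, h, rng)
            for c, h in zip(ch[::-1], cfg.heads[:cfg.n_stages][::-1])
        ]
        self.output_proj = nn.Conv2d(ch[0], 1, 3, rng, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        N, C, H, W = x.shape
        if C != 1:
            raise ValueError("expected a single-channel input")
        if not np.isfinite(x.data).all():
            raise FloatingPointError("non-finite network input")
        mult = cfg.pad_multiple
        ph = (-H) % mult
        pw = (-W) % mult
        if ph or pw:
            x = x.pad2d((0, ph, 0, pw), mode="reflect")
        h = ad.leaky_relu(self.input_proj(x), cfg.leaky_slope)
        skips = []
        for blocks, down in zip(self.enc_stages, self.downs):
            for blk in blocks:
                h = blk(h)
            skips.append(h)
            h = down(h)
        for blk in self.bottleneck:
            h = blk(h)
        for up, fuse, blocks, skip in zip(self.ups, self.fuses,
                                          self.dec_stages, skips[::-1]):
            h = up(h)
            h = fuse(ad.concatenate([h, skip], axis=1))
            for blk in blocks:
                h = blk(h)
        y = self.output_proj(h)
        if cfg.global_residual:
            y = y + x
        if ph or pw:
            y = y.crop2d(H, W)
        return y


def count_parameters(cfg: NetworkConfig) -> int:
    """Closed-form learnable-scalar count for a :class:`SwinTranslator`.

    Derived from the layer inventory; cross-checked against model
    introspection in the test suite.
    """
    def linear(i, o):
        return i * o + o

    def conv(ci, co, k):
        return co * ci * k * k + co

    def block(C, k_heads, M, e):
        attn = 4 * linear(C, C) + (2 * M - 1) ** 2 * k_heads
        leff = linear(C, e * C) + (e * C * 9 + e * C) + linear(e * C, C)
        norms = 2 * (2 * C)
        return attn + leff + norms

    M, e, nb = cfg.window_size, cfg.leff_expansion, cfg.blocks_per_stage
    ch = cfg.stage_channels
    cb = cfg.bottleneck_channels
    total = conv(1, ch[0], 3) + conv(ch[0], 1, 3)
    down_out = list(ch[1:]) + [cb]
    for i in range(cfg.n_stages):
        total += nb * block(ch[i], cfg.heads[i], M, e)
        total += conv(ch[i], down_out[i], 4)
    total += nb * block(cb, cfg.heads[-1], M, e)
    up_in = [cb] + list(ch[1:][::-1])
    for i, c in enumerate(ch[::-1]):
        total += up_in[i] * c * 4 + c                  # 2x2 transpose conv
        total += conv(2 * c, c, 1)                     # skip fusion
        total += nb * block(c, cfg.heads[:cfg.n_stages][::-1][i], M, e)
    return total
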