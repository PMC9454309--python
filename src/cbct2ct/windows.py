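"""Token/window bookkeeping for window-based self-attention.

A feature map is an ``N x C x H x W`` tensor.  Tokens are its spatial
positions flattened row-major into an ``N x (H*W) x C`` matrix.  Window
partitioning cuts the map into non-overlapping ``M x M`` tiles, each
flattened to ``M^2 x C``; the shifted variant rolls the map by ``-s`` in
both axes first and uses an additive attention mask so that content wrapped
across the image border never attends across the seam.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

MASK_NEG = -1e4  # large negative logit standing in for -inf


def img_to_tokens(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, H*W, C), row-major over spatial positions."""
    N, C, H, W = x.shape
    return x.transpose(0, 2, 3, 1).reshape(N, H * W, C)


def tokens_to_img(t: Tensor, H: int, W: int) -> Tensor:
    """(N, H*W, C) -> (N, C, H, W); exact inverse of :func:`img_to_tokens`."""
    N, T, C = t.shape
    if T != H * W:
        raise ValueError(f"token count {T} != H*W = {H * W}")
    return t.reshape(N, H, W, C).transpose(0, 3, 1, 2)


def partition_windows(x: Tensor, M: int) -> Tensor:
    """(N, C, H, W) -> (N * H/M * W/M, M^2, C) stack of window token blocks."""
    N, C, H, W = x.shape
    if H % M or W % M:
        raise ValueError(f"spatial dims {H}x{W} not divisible by window {M}")
    if M > H or M > W:
        raise ValueError(f"window {M} exceeds map {H}x{W}")
    t = x.transpose(0, 2, 3, 1)                       # N,H,W,C
    t = t.reshape(N, H // M, M, W // M, M, C)
    t = t.transpose(0, 1, 3, 2, 4, 5)                 # N,nh,nw,M,M,C
    return t.reshape(N * (H // M) * (W // M), M * M, C)


def merge_windows(w: Tensor, H: int, W: int) -> Tensor:
    """Inverse of :func:`partition_windows`."""
    B, T, C = w.shape
    M = int(round(np.sqrt(T)))
    if M * M != T:
        raise ValueError(f"window token count {T} is not a square")
    nh, nw = H // M, W // M
    N = B // (nh * nw)
    t = w.reshape(N, nh, nw, M, M, C)
    t = t.transpose(0, 1, 3, 2, 4, 5)                 # N,nh,M,nw,M,C
    t = t.reshape(N, H, W, C)
    return t.transpose(0, 3, 1, 2)


def cyclic_shift(x: Tensor, s: int) -> Tensor:
    """Roll both spatial axes by ``-s`` (element (i,j) moves to (i-s, j-s))."""
    if s == 0:
        return x
    return x.roll((-s, -s), axes=(-2, -1))


def cyclic_unshift(x: Tensor, s: int) -> Tensor:
    if s == 0:
        return x
    return x.roll((s, s), axes=(-2, -1))


def build_attention_mask(H: int, W: int, M: int, s: int) -> np.ndarray:
    """Additive logit mask for shifted-window attention.

    Returns an array of shape (n_windows, M^2, M^2) with 0 where a token
    pair may attend and :data:`MASK_NEG` where the pair originates from
    opposite sides of the cyclic-shift seam.
    """
    if not 0 < s < M:
        raise ValueError(f"shift must satisfy 0 < s < M, got s={s}, M={M}")
    if H % M or W % M:
        raise ValueError("map dims must be divisible by the window size")
    canvas = np.zeros((H, W), dtype=np.int64)
    cnt = 0
    bounds = (slice(0, H - M), slice(H - M, H - s), slice(H - s, None))
    wbounds = (slice(0, W - M), slice(W - M, W - s), slice(W - s, None))
    for hs in bounds:
        for ws in wbounds:
            canvas[hs, ws] = cnt
            cnt += 1
    ids = (canvas.reshape(H // M, M, W // M, M)
           .transpose(0, 2, 1, 3)
           .reshape(-1, M * M))
    diff = ids[:, :, None] != ids[:, None, :]
    return np.where(diff, MASK_NEG, 0.0).astype(np.float32)
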