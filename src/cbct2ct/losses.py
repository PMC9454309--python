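"""Composite training objective: Charbonnier plus multi-scale SSIM, mixed 9:1.

The Charbonnier term, mean over pixels of sqrt((y - x)^2 + eps^2) with
eps = 1e-3, is a smooth L1 surrogate that calibrates CT numbers; its eps
floor keeps the gradient finite at the minimum.  The MS-SSIM term compares
luminance (L), contrast (C) and structure (S) over a Gaussian local window
at a pyramid of dyadic scales:

    L = (2 u_x u_y + C1) / (u_x^2 + u_y^2 + C1)
    C = (2 s_x s_y + C2) / (s_x^2 + s_y^2 + C2)
    S = (s_xy + C3)   / (s_x s_y + C3)

    MS-SSIM = [L_M]^a_M * prod_j [C_j]^b_j [S_j]^g_j

with C1 = C2 = C3 = 1, contrast/structure pooled at every scale and
luminance only at the coarsest.  The objective is

    0.9 * Charbonnier + 0.1 * (1 - MS-SSIM).

All operations run on the autodiff engine, so the loss is differentiable
end to end; plain NumPy arrays are accepted and wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

#: Standard five-scale exponent vector; truncated + renormalized for fewer scales.
FIVE_SCALE_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass(frozen=True)
class LossConfig:
    epsilon: float = 1e-3              # Charbonnier constant
    c1: float = 1.0                    # SSIM luminance constant
    c2: float = 1.0                    # SSIM contrast constant
    c3: float = 1.0                    # SSIM structure constant
    n_scales: int = 3                  # MS-SSIM pyramid depth
    scale_weights: tuple[float, ...] | None = None  # None -> truncated standard
    mix: tuple[float, float] = (0.9, 0.1)           # (charbonnier, ms-ssim)
    ssim_window: int = 11              # Gaussian window side
    ssim_sigma: float = 1.5            # Gaussian window std, pixels
    charbonnier_form: str = "mean"     # "mean" (per-pixel) or "norm" (per-image)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_scales < 1:
            raise ValueError("need at least one scale")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("mix weights must sum to 1")
        if self.charbonnier_form not in ("mean", "norm"):
            raise ValueError("charbonnier_form must be 'mean' or 'norm'")

    def weights(self) -> np.ndarray:
        if self.scale_weights is not None:
            w = np.asarray(self.scale_weights, dtype=np.float64)
            if len(w) != self.n_scales:
                raise ValueError("need one scale weight per scale")
        else:
            w = np.asarray(FIVE_SCALE_WEIGHTS[:self.n_scales])
        return w / w.sum()

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon, "c1": self.c1, "c2": self.c2,
            "c3": self.c3, "n_scales": self.n_scales,
            "scale_weights": (list(self.scale_weights)
                              if self.scale_weights else None),
            "mix": list(self.mix), "ssim_window": self.ssim_window,
            "ssim_sigma": self.ssim_sigma,
            "charbonnier_form": self.charbonnier_form,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        d = dict(d)
        if d.get("scale_weights"):
            d["scale_weights"] = tuple(d["scale_weights"])
        if "mix" in d:
            d["mix"] = tuple(d["mix"])
        return cls(**d)


def _as_nchw(x) -> Tensor:
    """Canonical (N,1,H,W) float64 view; the loss arithmetic runs in
    double precision so its closed forms are exact to ~1e-15 even when the
    network activations are float32."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    t = ad.cast(t, np.float64)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, *t.shape[1:])
    elif t.ndim != 4:
        raise ValueError(f"expected 2D-4D image input, got ndim={t.ndim}")
    return t


def charbonnier(pred, target, epsilon: float = 1e-3,
                form: str = "mean") -> Tensor:
    """sqrt((pred - target)^2 + eps^2), reduced over pixels."""
    p, t = _as_nchw(pred), _as_nchw(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    d = p - t
    if form == "mean":
        return ((d * d + epsilon * epsilon).sqrt()).mean()
    return ((d * d).sum() + epsilon * epsilon).sqrt()


def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    r = np.arange(window, dtype=np.float64) - (window - 1) / 2.0
    g = np.exp(-0.5 * (r / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _local_filter(x: Tensor, kernel: np.ndarray) -> Tensor:
    w = Tensor(kernel[None, None], dtype=x.data.dtype)  # fixed, not learned
    return ad.conv2d(x, w)                              # valid convolution


def ssim_components(x, y, cfg: LossConfig = LossConfig()
                    ) -> tuple[Tensor, Tensor, Tensor]:
    """Per-pixel luminance, contrast and structure comparison maps."""
    xt, yt = _as_nchw(x), _as_nchw(y)
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch {xt.shape} vs {yt.shape}")
    H, W = xt.shape[-2:]
    if cfg.ssim_window > H or cfg.ssim_window > W:
        raise ValueError(f"SSIM window {cfg.ssim_window} exceeds image "
                         f"{H}x{W}")
    k = _gaussian_kernel(cfg.ssim_window, cfg.ssim_sigma)
    ux = _local_filter(xt, k)
    uy = _local_filter(yt, k)
    # local second moments; tiny negative values from cancellation are clipped
    vx = (_local_filter(xt * xt, k) - ux * ux).clip_min(0.0)
    vy = (_local_filter(yt * yt, k) - uy * uy).clip_min(0.0)
    cov = _local_filter(xt * yt, k) - ux * uy
    sx, sy = vx.sqrt(), vy.sqrt()
    L = (2.0 * ux * uy + cfg.c1) / (ux * ux + uy * uy + cfg.c1)
    C = (2.0 * sx * sy + cfg.c2) / (vx + vy + cfg.c2)
    S = (cov + cfg.c3) / (sx * sy + cfg.c3)
    return L, C, S


def ms_ssim(x, y, cfg: LossConfig = LossConfig()) -> Tensor:
    """Multi-scale SSIM in (0, 1]; 1 iff the images coincide."""
    xt, yt = _as_nchw(x), _as_nchw(y)
    H, W = xt.shape[-2:]
    smallest = min(H, W) // 2 ** (cfg.n_scales - 1)
    if smallest < cfg.ssim_window:
        raise ValueError(
            f"{cfg.n_scales} scales reduce a {H}x{W} image below the "
            f"{cfg.ssim_window}-px SSIM window")
    w = cfg.weights()
    total: Tensor | float = 1.0
    for j in range(cfg.n_scales):
        L, C, S = ssim_components(xt, yt, cfg)
        # exponentiation needs a positive base; means can graze zero
        cs = (C.mean().clip_min(1e-6) ** float(w[j])) * \
             (S.mean().clip_min(1e-6) ** float(w[j]))
        total = total * cs
        if j == cfg.n_scales - 1:
            total = total * (L.mean().clip_min(1e-6) ** float(w[j]))
        else:
            xt, yt = ad.avg_pool2x2(xt), ad.avg_pool2x2(yt)
    return total


def composite_loss(pred, target, cfg: LossConfig = LossConfig(),
                   return_parts: bool = False):
    """0.9 * Charbonnier + 0.1 * (1 - MS-SSIM) (weights from ``cfg.mix``)."""
    wc, wm = cfg.mix
    ch = charbonnier(pred, target, cfg.epsilon, cfg.charbonnier_form)
    if wm == 0.0:
        total = wc * ch
        if return_parts:
            return total, ch, None
        return total
    ms = ms_ssim(pred, target, cfg)
    total = wc * ch + wm * (1.0 - ms)
    if return_parts:
        return total, ch, ms
    return total
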