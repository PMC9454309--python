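"""Preprocessing, the Lookahead-over-Adam training loop, and inference.

HU images are clipped to a configurable range (default -1000..1000 HU) and
affinely mapped to [-1, 1]; pixels outside the body mask are forced to 0 HU
*before* the mapping, mirroring the zero-background pairing convention.
The optimizer is Adam (lr 0.001) wrapped in Lookahead (k = 5, alpha = 0.5):
the fast weights take an Adam step every iteration and every k-th step the
slow weights move a fraction alpha toward them, after which the fast
weights restart from the slow ones.

Inference (:func:`synthesize`) runs the network slice by slice, maps the
output back to HU and re-zeroes the background; when no body mask is given
one is estimated from the input CBCT (threshold > -300 HU, largest
connected component, holes filled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .losses import LossConfig, composite_loss
from .transformer import NetworkConfig, SwinTranslator


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    lookahead_k: int = 5
    lookahead_alpha: float = 0.5
    batch_size: int = 4
    n_epochs: int = 10
    steps_per_epoch: int | None = None     # None -> one pass over the data
    crop_size: int | None = None           # random square crops if set
    hu_range: tuple[float, float] = (-1000.0, 1000.0)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.lookahead_alpha <= 1:
            raise ValueError("lookahead alpha must be in (0, 1]")
        if self.lookahead_k < 1:
            raise ValueError("lookahead k must be >= 1")
        if self.hu_range[0] >= self.hu_range[1]:
            raise ValueError("hu_range must satisfy lo < hi")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["hu_range"] = list(self.hu_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "hu_range" in d:
            d["hu_range"] = tuple(d["hu_range"])
        return cls(**d)


# ----------------------------------------------------------- preprocessing
def normalize_hu(values: np.ndarray, hu_range=(-1000.0, 1000.0),
                 body_mask: np.ndarray | None = None) -> np.ndarray:
    """Clip to ``hu_range`` and map affinely to [-1, 1].

    Background pixels (outside ``body_mask``) are set to 0 HU first, so
    they land at the image of 0 HU on the normalized scale.
    """
    lo, hi = hu_range
    if lo >= hi:
        raise ValueError("degenerate HU range")
    arr = np.asarray(values)
    out_dtype = np.float64 if arr.dtype == np.float64 else np.float32
    v = arr.astype(np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite HU values")
    if body_mask is not None:
        v = np.where(body_mask, v, 0.0)
    v = np.clip(v, lo, hi)
    return ((v - lo) / (hi - lo) * 2.0 - 1.0).astype(out_dtype)


def denormalize_hu(values: np.ndarray,
                   hu_range=(-1000.0, 1000.0)) -> np.ndarray:
    """Exact inverse of the affine part of :func:`normalize_hu`."""
    lo, hi = hu_range
    if lo >= hi:
        raise ValueError("degenerate HU range")
    arr = np.asarray(values)
    out_dtype = np.float64 if arr.dtype == np.float64 else np.float32
    v = arr.astype(np.float64)
    return ((v + 1.0) / 2.0 * (hi - lo) + lo).astype(out_dtype)


def estimate_body_mask(hu_slice: np.ndarray,
                       threshold: float = -300.0) -> np.ndarray:
    """Body = largest connected component above ``threshold``, holes filled."""
    rough = np.asarray(hu_slice) > threshold
    if not rough.any():
        return rough
    lbl, n = ndimage.label(rough)
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    body = lbl == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(body)


# -------------------------------------------------------------- optimizers
class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bc1)
                       / (np.sqrt(v / bc2) + self.eps)).astype(p.data.dtype)

    def state(self) -> dict:
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}


class Lookahead:
    """Lookahead wrapper: slow weights chase the fast (inner-Adam) weights."""

    def __init__(self, inner: Adam, k: int = 5, alpha: float = 0.5):
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        self.inner = inner
        self.k, self.alpha = k, alpha
        self.counter = 0
        self.slow = [p.data.copy() for p in inner.params]

    def step(self):
        self.inner.step()
        self.counter += 1
        if self.counter % self.k == 0:
            for p, s in zip(self.inner.params, self.slow):
                s += self.alpha * (p.data - s)
                p.data = s.copy()

    def slow_weights(self) -> list[np.ndarray]:
        return [s.copy() for s in self.slow]


def lookahead_step(fast_params, slow_params, inner_update, k: int,
                   alpha: float, step_index: int):
    """One functional Lookahead iteration over parameter lists.

    ``inner_update`` maps the fast parameter list to its updated value
    (e.g. one Adam step).  On every ``k``-th step (1-based ``step_index``)
    the slow weights interpolate toward the fast ones and the fast weights
    are reset onto them.
    """
    fast = [np.asarray(f, dtype=np.float64).copy()
            for f in inner_update(fast_params)]
    slow = [np.asarray(s, dtype=np.float64).copy() for s in slow_params]
    if step_index % k == 0:
        slow = [s + alpha * (f - s) for f, s in zip(fast, slow)]
        fast = [s.copy() for s in slow]
    return fast, slow


# ------------------------------------------------------------- checkpoints
@dataclass
class Checkpoint:
    """Slow weights + configs + training trace, round-trippable to one file."""

    network_config: NetworkConfig
    state: dict[str, np.ndarray]
    loss_config: LossConfig
    train_config: TrainConfig
    epoch: int
    history: dict[str, list[float]]
    opt_state: dict[str, np.ndarray] = field(default_factory=dict)

    def save(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps({
            "network": self.network_config.to_dict(),
            "loss": self.loss_config.to_dict(),
            "train": self.train_config.to_dict(),
            "epoch": self.epoch,
            "history": self.history,
            "version": 1,
        })
        opt = {f"__opt__{k}": v for k, v in self.opt_state.items()}
        np.savez_compressed(path, __meta__=np.frombuffer(
            meta.encode(), dtype=np.uint8), **self.state, **opt)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {k: z[k] for k in z.files
                     if k != "__meta__" and not k.startswith("__opt__")}
            opt = {k[len("__opt__"):]: z[k] for k in z.files
                   if k.startswith("__opt__")}
        return cls(
            network_config=NetworkConfig.from_dict(meta["network"]),
            state=state,
            loss_config=LossConfig.from_dict(meta["loss"]),
            train_config=TrainConfig.from_dict(meta["train"]),
            epoch=meta["epoch"],
            history={k: list(v) for k, v in meta["history"].items()},
            opt_state=opt,
        )

    def build_model(self) -> SwinTranslator:
        model = SwinTranslator(self.network_config,
                               np.random.default_rng(0))
        model.load_state_dict(self.state)
        return model


# ------------------------------------------------------------ training loop
def _opt_snapshot(model, opt: "Lookahead") -> dict[str, np.ndarray]:
    snap = {"adam_t": np.asarray(opt.inner.t),
            "lookahead_counter": np.asarray(opt.counter)}
    for (name, _), m, v in zip(model.named_parameters(),
                               opt.inner.m, opt.inner.v):
        snap[f"adam_m.{name}"] = m.copy()
        snap[f"adam_v.{name}"] = v.copy()
    return snap


def _batch_tensor(stack: np.ndarray) -> Tensor:
    return Tensor(stack[:, None, :, :].astype(np.float32))


def _eval_loss(model, x: np.ndarray, y: np.ndarray, loss_cfg: LossConfig,
               batch: int = 4) -> float:
    total, n = 0.0, 0
    with no_grad():
        for i in range(0, len(x), batch):
            xb, yb = x[i:i + batch], y[i:i + batch]
            pred = model(_batch_tensor(xb))
            loss = composite_loss(pred, _batch_tensor(yb), loss_cfg)
            total += float(loss.data) * len(xb)
            n += len(xb)
    return total / max(n, 1)


def train_on_arrays(cbct: np.ndarray, ct: np.ndarray,
                    net_cfg: NetworkConfig, loss_cfg: LossConfig,
                    train_cfg: TrainConfig,
                    val: tuple[np.ndarray, np.ndarray] | None = None,
                    log_path=None) -> Checkpoint:
    """Fit the translator on pre-normalized slice stacks of shape (n, H, W).

    Inputs must already be on the [-1, 1] scale with zeroed background
    (see :func:`normalize_hu`).  Returns the best-validation checkpoint
    (final weights when no validation split is given).
    """
    if len(cbct) == 0:
        raise ValueError("empty training split")
    if cbct.shape != ct.shape:
        raise ValueError("CBCT and CT stacks must share shape")
    rng = np.random.default_rng(train_cfg.seed)
    model = SwinTranslator(net_cfg, rng)
    inner = Adam(model.parameters(), lr=train_cfg.learning_rate,
                 betas=(train_cfg.beta1, train_cfg.beta2),
                 eps=train_cfg.adam_eps)
    opt = Lookahead(inner, k=train_cfg.lookahead_k,
                    alpha=train_cfg.lookahead_alpha)

    n = len(cbct)
    bs = min(train_cfg.batch_size, n)
    history: dict[str, list[float]] = {"train": [], "val": [],
                                       "step_loss": []}
    log_rows: list[str] = ["step,charbonnier,ms_ssim,composite"]
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    step = 0

    for epoch in range(train_cfg.n_epochs):
        order = rng.permutation(n)
        batches = [order[i:i + bs] for i in range(0, n, bs)]
        if train_cfg.steps_per_epoch is not None:
            while len(batches) < train_cfg.steps_per_epoch:
                batches.append(rng.choice(n, size=bs, replace=False)
                               if bs < n else np.arange(n))
            batches = batches[:train_cfg.steps_per_epoch]
        epoch_losses = []
        for idx in batches:
            xb, yb = cbct[idx], ct[idx]
            if train_cfg.crop_size is not None:
                cs = train_cfg.crop_size
                H, W = xb.shape[1:]
                r0 = rng.integers(0, H - cs + 1)
                c0 = rng.integers(0, W - cs + 1)
                xb = xb[:, r0:r0 + cs, c0:c0 + cs]
                yb = yb[:, r0:r0 + cs, c0:c0 + cs]
            model.zero_grad()
            pred = model(_batch_tensor(xb))
            loss, ch, ms = composite_loss(pred, _batch_tensor(yb), loss_cfg,
                                          return_parts=True)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss at step {step} (epoch {epoch}); "
                    "try a lower learning rate")
            loss.backward()
            opt.step()
            step += 1
            epoch_losses.append(lval)
            history["step_loss"].append(lval)
            log_rows.append(
                f"{step},{float(ch.data):.6f},"
                f"{float(ms.data) if ms is not None else 1.0:.6f},{lval:.6f}")
        history["train"].append(float(np.mean(epoch_losses)))
        if val is not None:
            vloss = _eval_loss(model, val[0], val[1], loss_cfg)
            history["val"].append(vloss)
            if vloss < best_val:
                best_val = vloss
                # checkpoint the slow (Lookahead) weights
                best_state = {k: s.copy() for (k, _), s in
                              zip(model.named_parameters(),
                                  opt.slow)}
                best_opt = _opt_snapshot(model, opt)
                best_epoch = epoch

    if val is None or not history["val"]:
        best_state = {k: s.copy() for (k, _), s in
                      zip(model.named_parameters(), opt.slow)}
        best_opt = _opt_snapshot(model, opt)
        best_epoch = train_cfg.n_epochs - 1

    if log_path is not None:
        Path(log_path).parent.mkdir(parents=True, exist_ok=True)
        Path(log_path).write_text("\n".join(log_rows) + "\n")

    return Checkpoint(network_config=net_cfg, state=best_state,
                      loss_config=loss_cfg, train_config=train_cfg,
                      epoch=best_epoch, history=history,
                      opt_state=best_opt)


def load_manifest_split(manifest_path, split: str,
                        limit: int | None = None):
    """Load (cbct, ct, body) stacks for one split of a dataset manifest."""
    import pandas as pd

    from .io import read_volume

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    rows = df[df["split"] == split]
    if limit is not None:
        rows = rows.iloc[:limit]
    if len(rows) == 0:
        raise ValueError(f"empty split '{split}' in {manifest_path}")
    base = manifest_path.parent
    cbct, ct, body = [], [], []
    for _, r in rows.iterrows():
        cbct.append(read_volume(base / r["cbct"], squeeze=True)[0])
        ct.append(read_volume(base / r["ct"], squeeze=True)[0])
        body.append(read_volume(base / r["mask_body"], squeeze=True)[0] > 0)
    return np.stack(cbct), np.stack(ct), np.stack(body)


def train(manifest_path, net_cfg: NetworkConfig, loss_cfg: LossConfig,
          train_cfg: TrainConfig, checkpoint_path=None,
          log_path=None) -> Checkpoint:
    """Train from a dataset manifest (train/val splits), save best checkpoint."""
    tr_cbct, tr_ct, tr_body = load_manifest_split(manifest_path, "train")
    try:
        va = load_manifest_split(manifest_path, "val")
    except ValueError:
        va = None
    hu = train_cfg.hu_range

    def prep(stackx, stacky, bodies):
        x = np.stack([normalize_hu(s, hu, m)
                      for s, m in zip(stackx, bodies)])
        y = np.stack([normalize_hu(s, hu, m)
                      for s, m in zip(stacky, bodies)])
        return x, y

    x, y = prep(tr_cbct, tr_ct, tr_body)
    val = prep(va[0], va[1], va[2]) if va is not None else None
    ckpt = train_on_arrays(x, y, net_cfg, loss_cfg, train_cfg, val=val,
                           log_path=log_path)
    if checkpoint_path is not None:
        ckpt.save(checkpoint_path)
    return ckpt


# --------------------------------------------------------------- inference
def synthesize(cbct_volume: np.ndarray, checkpoint: Checkpoint,
               body_masks: np.ndarray | None = None,
               batch: int = 4) -> np.ndarray:
    """Slice-wise CBCT -> synthetic CT in HU; background re-zeroed.

    ``cbct_volume`` is (D, H, W) (or a single (H, W) slice) in HU.  The
    output shares the input grid exactly.
    """
    vol = np.asarray(cbct_volume, dtype=np.float32)
    single = vol.ndim == 2
    if single:
        vol = vol[None]
    if body_masks is None:
        body_masks = np.stack([estimate_body_mask(s) for s in vol])
    elif body_masks.ndim == 2:
        body_masks = body_masks[None]
    model = checkpoint.build_model()
    hu = checkpoint.train_config.hu_range
    out = np.empty_like(vol)
    with no_grad():
        for i in range(0, len(vol), batch):
            xs = np.stack([normalize_hu(s, hu, m) for s, m in
                           zip(vol[i:i + batch], body_masks[i:i + batch])])
            pred = model(_batch_tensor(xs)).data[:, 0]
            hu_pred = denormalize_hu(pred, hu)
            hu_pred[~body_masks[i:i + batch]] = 0.0
            out[i:i + batch] = hu_pred
    return out[0] if single else out
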