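"""Scikit-learn style estimator facade over the translation network.

:class:`CBCTCorrector` exposes the full pipeline as fit/predict on stacks
of HU slices, so it composes with sklearn model-selection utilities.  All
hyperparameters are plain constructor arguments (``get_params`` /
``set_params`` work as usual); fitted state lives in trailing-underscore
attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .losses import LossConfig
from .training import (Checkpoint, TrainConfig, normalize_hu,
                       synthesize, train_on_arrays)
from .transformer import NetworkConfig


class CBCTCorrector(BaseEstimator):
    """CBCT -> synthetic-CT slice translator.

    Parameters
    ----------
    base_channels, window_size, heads, channel_multipliers, leff_expansion
        Architecture of the windowed-attention encoder-decoder.
    epsilon, n_scales, mix
        Composite-loss settings (Charbonnier constant, MS-SSIM scale count,
        and the Charbonnier:MS-SSIM mixing weights).
    learning_rate, lookahead_k, lookahead_alpha, batch_size, n_epochs,
    steps_per_epoch, crop_size
        Optimization settings (Adam inside Lookahead).
    hu_range
        HU clipping window mapped to [-1, 1].
    random_state
        Master seed for initialization and data order.
    """

    def __init__(self, base_channels: int = 16, window_size: int = 4,
                 heads: tuple[int, ...] = (1, 2, 4, 8, 8),
                 channel_multipliers: tuple[int, ...] = (1, 2, 4, 8),
                 bottleneck_multiplier: int = 16,
                 leff_expansion: int = 2,
                 epsilon: float = 1e-3, n_scales: int = 3,
                 mix: tuple[float, float] = (0.9, 0.1),
                 learning_rate: float = 0.001,
                 lookahead_k: int = 5, lookahead_alpha: float = 0.5,
                 batch_size: int = 4, n_epochs: int = 10,
                 steps_per_epoch: int | None = None,
                 crop_size: int | None = None,
                 hu_range: tuple[float, float] = (-1000.0, 1000.0),
                 random_state: int = 0):
        self.base_channels = base_channels
        self.window_size = window_size
        self.heads = heads
        self.channel_multipliers = channel_multipliers
        self.bottleneck_multiplier = bottleneck_multiplier
        self.leff_expansion = leff_expansion
        self.epsilon = epsilon
        self.n_scales = n_scales
        self.mix = mix
        self.learning_rate = learning_rate
        self.lookahead_k = lookahead_k
        self.lookahead_alpha = lookahead_alpha
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.steps_per_epoch = steps_per_epoch
        self.crop_size = crop_size
        self.hu_range = hu_range
        self.random_state = random_state

    # ------------------------------------------------------------- configs
    def _configs(self):
        net = NetworkConfig(
            base_channels=self.base_channels,
            window_size=self.window_size,
            heads=tuple(self.heads),
            channel_multipliers=tuple(self.channel_multipliers),
            bottleneck_multiplier=self.bottleneck_multiplier,
            leff_expansion=self.leff_expansion,
        )
        loss = LossConfig(epsilon=self.epsilon, n_scales=self.n_scales,
                          mix=tuple(self.mix))
        train = TrainConfig(
            learning_rate=self.learning_rate,
            lookahead_k=self.lookahead_k,
            lookahead_alpha=self.lookahead_alpha,
            batch_size=self.batch_size, n_epochs=self.n_epochs,
            steps_per_epoch=self.steps_per_epoch,
            crop_size=self.crop_size,
            hu_range=tuple(self.hu_range), seed=self.random_state,
        )
        return net, loss, train

    # ----------------------------------------------------------------- fit
    def fit(self, X, y, body_masks=None, validation=None):
        """Train on paired HU slice stacks.

        Parameters
        ----------
        X : (n, H, W) array of CBCT slices in HU.
        y : (n, H, W) array of matching CT slices in HU.
        body_masks : optional (n, H, W) boolean array; None estimates them.
        validation : optional (X_val, y_val, masks_val) triple.
        """
        from .training import estimate_body_mask

        X = np.asarray(X, np.float32)
        y = np.asarray(y, np.float32)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X and y must be matching (n, H, W) stacks")
        if body_masks is None:
            body_masks = np.stack([estimate_body_mask(s) for s in X])
        net, loss, train = self._configs()
        hu = train.hu_range

        def prep(a, b, m):
            xa = np.stack([normalize_hu(s, hu, mm) for s, mm in zip(a, m)])
            xb = np.stack([normalize_hu(s, hu, mm) for s, mm in zip(b, m)])
            return xa, xb

        xn, yn = prep(X, y, body_masks)
        val = None
        if validation is not None:
            vx, vy, vm = validation
            if vm is None:
                vm = np.stack([estimate_body_mask(s) for s in vx])
            val = prep(np.asarray(vx, np.float32),
                       np.asarray(vy, np.float32), vm)
        self.checkpoint_ = train_on_arrays(xn, yn, net, loss, train, val=val)
        self.loss_history_ = self.checkpoint_.history
        self.n_parameters_ = self.checkpoint_.build_model().n_parameters()
        return self

    # ------------------------------------------------------------- predict
    def predict(self, X, body_masks=None):
        """Translate CBCT HU slices to synthetic CT HU slices."""
        if not hasattr(self, "checkpoint_"):
            raise RuntimeError("estimator is not fitted")
        return synthesize(np.asarray(X, np.float32), self.checkpoint_,
                          body_masks=body_masks)

    def save(self, path):
        self.checkpoint_.save(path)

    @classmethod
    def from_checkpoint(cls, path) -> "CBCTCorrector":
        ckpt = Checkpoint.load(path)
        est = cls()
        est.checkpoint_ = ckpt
        est.loss_history_ = ckpt.history
        est.n_parameters_ = ckpt.build_model().n_parameters()
        return est
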