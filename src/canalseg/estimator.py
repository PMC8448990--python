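"""scikit-learn style estimator wrapping the whole pipeline.

``CanalSegmenter`` is the package's primary API: construct with
hyperparameters, ``fit`` on a list of labelled volumes, ``predict`` binary
masks for new volumes.  It follows the scikit-learn estimator contract
(``get_params``/``set_params``, fitted attributes with a trailing
underscore, ``clone``-ability), so it composes with sklearn model
selection; the functional trainer/inference modules underneath remain
usable directly.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .inference import SlidingSpec, evaluate_cases, predict_volume
from .metrics import dsc
from .network import NetworkConfig
from .phantoms import LabeledVolume
from .training import TrainingConfig, model_from_checkpoint, train

__all__ = ["CanalSegmenter"]


def _as_volumes(X, y, spacing_mm):
    if y is None:
        if not all(isinstance(v, LabeledVolume) for v in X):
            raise ValueError("y may only be omitted when X holds LabeledVolumes")
        return list(X)
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} volumes but y has {len(y)} label grids")
    return [v if isinstance(v, LabeledVolume) else
            LabeledVolume(intensities=np.asarray(v, dtype=np.float32),
                          labels=np.asarray(lbl, dtype=np.uint8),
                          spacing_mm=spacing_mm)
            for v, lbl in zip(X, y)]


class CanalSegmenter(BaseEstimator):
    """Attention 3D U-Net segmenter with sliding-window inference.

    Parameters mirror the network/training/inference configuration
    dataclasses; see those for semantics.  ``X`` in ``fit``/``predict`` is
    a list of 3D intensity arrays (depth-first) or
    :class:`~canalseg.phantoms.LabeledVolume` instances; ``y`` a matching
    list of binary label grids (omit when X holds LabeledVolumes).

    Attributes (after fit): ``model_`` the trained network, ``history_``
    the loss/validation trace, ``checkpoint_`` the self-describing
    weights+config dict.
    """

    def __init__(self, variant: str = "sequential_spatial_first",
                 encoder_channels: tuple = (32, 64, 128, 256),
                 n_pool: int = 3,
                 gau_upsample_mode: str = "isotropic",
                 sse_on_bottleneck: bool = True,
                 patch_size: tuple = (32, 64, 64),
                 batch_size: int = 8,
                 learning_rate: float = 1e-4,
                 weight_decay: float = 5e-4,
                 beta1: float = 0.97,
                 optimizer: str = "adam",
                 max_steps: int = 1000,
                 validation_interval: int = 200,
                 smooth: float = 1e-5,
                 normalize: bool = True,
                 sliding_steps: tuple = (8, 28, 28),
                 threshold: float = 0.5,
                 spacing_mm: tuple = (1.0, 1.0, 1.0),
                 validation_fraction: float = 0.0,
                 seed: int = 0):
        self.variant = variant
        self.encoder_channels = encoder_channels
        self.n_pool = n_pool
        self.gau_upsample_mode = gau_upsample_mode
        self.sse_on_bottleneck = sse_on_bottleneck
        self.patch_size = patch_size
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.beta1 = beta1
        self.optimizer = optimizer
        self.max_steps = max_steps
        self.validation_interval = validation_interval
        self.smooth = smooth
        self.normalize = normalize
        self.sliding_steps = sliding_steps
        self.threshold = threshold
        self.spacing_mm = spacing_mm
        self.validation_fraction = validation_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    def _configs(self):
        net = NetworkConfig(encoder_channels=tuple(self.encoder_channels),
                            n_pool=self.n_pool, variant=self.variant,
                            gau_upsample_mode=self.gau_upsample_mode,
                            sse_on_bottleneck=self.sse_on_bottleneck,
                            seed=self.seed)
        sliding = SlidingSpec(patch_size=tuple(self.patch_size),
                              steps=tuple(self.sliding_steps),
                              threshold=self.threshold)
        cfg = TrainingConfig(patch_size=tuple(self.patch_size),
                             batch_size=self.batch_size,
                             learning_rate=self.learning_rate,
                             weight_decay=self.weight_decay,
                             beta1=self.beta1, optimizer=self.optimizer,
                             max_steps=self.max_steps,
                             validation_interval=self.validation_interval,
                             smooth=self.smooth, normalize=self.normalize,
                             seed=self.seed, sliding=sliding)
        return net, cfg, sliding

    def fit(self, X, y=None):
        volumes = _as_volumes(X, y, tuple(self.spacing_mm))
        net, cfg, _ = self._configs()
        n_val = int(round(self.validation_fraction * len(volumes)))
        if n_val > 0 and len(volumes) > n_val:
            train_set, val_set = volumes[:-n_val], volumes[-n_val:]
        else:
            train_set, val_set = volumes, None
        self.checkpoint_, self.history_ = train(net, cfg, train_set, val_set)
        self.model_ = model_from_checkpoint(self.checkpoint_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this CanalSegmenter instance is not fitted yet")

    def predict(self, X):
        """Binary masks for a list of volumes."""
        self._check_fitted()
        _, _, sliding = self._configs()
        return [predict_volume(self.model_, v, sliding, normalize=self.normalize)[2]
                for v in X]

    def predict_proba(self, X):
        """Per-voxel foreground probability maps."""
        self._check_fitted()
        _, _, sliding = self._configs()
        return [predict_volume(self.model_, v, sliding, normalize=self.normalize)[0]
                for v in X]

    def score(self, X, y=None):
        """Mean Dice similarity coefficient over the given volumes."""
        self._check_fitted()
        volumes = _as_volumes(X, y, tuple(self.spacing_mm))
        masks = self.predict(volumes)
        return float(np.mean([dsc(m, v.labels) for m, v in zip(masks, volumes)]))

    def evaluate(self, X, y=None):
        """Per-case + mean DSC/AVD/ASD report (DataFrame)."""
        self._check_fitted()
        volumes = _as_volumes(X, y, tuple(self.spacing_mm))
        _, _, sliding = self._configs()
        return evaluate_cases(self.model_, volumes, sliding, normalize=self.normalize)
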