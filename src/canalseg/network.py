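"""Attention-augmented 3D U-Net for semicircular-canal segmentation.

The model is a 3D U-Net encoder-decoder whose skip connections are replaced
by attention modules:

* **3D spatial squeeze-and-excitation (sSE)** — a 3x3x3 convolution squeezes
  the channels of an encoder feature map ``U0`` to a single-channel
  projection ``U1``; its sigmoid gates every spatial location:
  ``U2 = sigmoid(U1) * U0``.
* **3D global attention upsample (GAU)** — the high-level feature map ``F2``
  is globally average-pooled and projected (1x1x1 conv + BN + ReLU) to a
  per-channel gate ``W1``; the low-level map ``F1`` is transformed by a
  1x1x1 conv + BN + ReLU to ``F3`` and gated channel-wise; ``F2`` is
  upsampled by a transposed convolution to ``F4``; the block outputs
  ``F5 = W1 * F3 + F4``.

Six wiring variants are provided for ablation: a plain 3D U-Net baseline
(transposed-conv + concatenation skips), GAU-only and sSE-only networks, the
two sequential attention orders (spatial-first is the default, and the best
performer), and the parallel sum of both modules.

The encoder uses double 3x3x3 conv + BN + ReLU blocks at channel widths
32/64/128/256 separated by 2x2x2 max pooling (three poolings = 8x
downsampling at the bottleneck); the head is a 1x1x1 convolution to
single-channel logits at full input resolution.

Because the printed GAU transposed convolution (kernel [1,4,4], stride
[1,2,2]) cannot restore a depth axis halved by 2x2x2 pooling, the default
``gau_upsample_mode='isotropic'`` uses kernel [4,4,4]/stride [2,2,2];
``'paper_literal'`` keeps the anisotropic upsample and pairs it with
[1,2,2] pooling so the network remains shape-consistent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (BatchNorm3d, Conv3d, ConvTranspose3d, Module, Tensor,
                 concat, global_avg_pool3d, max_pool3d, relu, sigmoid)

__all__ = [
    "VARIANTS", "NetworkConfig", "ConfigurationError", "ShapeError",
    "ConvBlock", "SpatialSE", "GAU3d", "combine_attention",
    "AttentionUNet3D", "build_network", "save_checkpoint", "load_checkpoint",
]

VARIANTS = (
    "baseline_3dunet",
    "gau_only",
    "sse_only",
    "sequential_spatial_first",
    "sequential_channel_first",
    "parallel",
)

GAU_VARIANTS = ("gau_only", "sequential_spatial_first",
                "sequential_channel_first", "parallel")
SSE_VARIANTS = ("sse_only", "sequential_spatial_first",
                "sequential_channel_first", "parallel")


class ConfigurationError(ValueError):
    """Invalid network configuration or incompatible input geometry."""


class ShapeError(ValueError):
    """Feature-map shape mismatch inside an attention block."""


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    encoder_channels: per-level widths, length ``n_pool + 1``; the default
        continues the paper-stated 32/64/128 doubling into a 256-channel
        bottleneck.
    variant: one of :data:`VARIANTS`; the default is the spatial-first
        sequential arrangement (the best arrangement in the ablation).
    gau_upsample_mode: 'isotropic' or 'paper_literal' (see module docstring).
    sse_on_bottleneck: whether sSE also gates the bottleneck feature map
        before the first GAU in sSE-containing attention variants.
    """

    in_channels: int = 1
    encoder_channels: tuple = (32, 64, 128, 256)
    n_pool: int = 3
    variant: str = "sequential_spatial_first"
    gau_upsample_mode: str = "isotropic"
    sse_on_bottleneck: bool = True
    seed: int = 0

    def __post_init__(self):
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        if len(self.encoder_channels) != self.n_pool + 1:
            raise ConfigurationError(
                f"encoder_channels must have n_pool+1={self.n_pool + 1} entries, "
                f"got {len(self.encoder_channels)}")
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; valid: {', '.join(VARIANTS)}")
        if self.gau_upsample_mode not in ("isotropic", "paper_literal"):
            raise ConfigurationError(
                f"unknown gau_upsample_mode {self.gau_upsample_mode!r}")

    @property
    def pool_factors(self) -> tuple:
        """Per-axis pooling factor applied between consecutive levels."""
        if self.gau_upsample_mode == "paper_literal" and self.variant in GAU_VARIANTS:
            return (1, 2, 2)
        return (2, 2, 2)

    @property
    def downsampling(self) -> tuple:
        f = self.pool_factors
        return tuple(x ** self.n_pool for x in f)


class ConvBlock(Module):
    """Two (3x3x3 conv -> BN -> ReLU) stages; spatial size preserved."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(in_channels, out_channels, 3, rng=rng)
        self.bn1 = BatchNorm3d(out_channels)
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng=rng)
        self.bn2 = BatchNorm3d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        x = relu(self.bn1(self.conv1(x)))
        return relu(self.bn2(self.conv2(x)))


class SpatialSE(Module):
    """3D spatial squeeze-and-excitation gate: ``U2 = sigmoid(U1) * U0``."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.squeeze = Conv3d(channels, 1, 3, rng=rng)

    def gate(self, U0: Tensor) -> Tensor:
        """The spatial attention map sigmoid(U1), values in (0, 1)."""
        return sigmoid(self.squeeze(U0))

    def forward(self, U0: Tensor) -> Tensor:
        return self.gate(U0) * U0


class GAU3d(Module):
    """3D global attention upsample fusing a low/high-level feature pair."""

    def __init__(self, c_low: int, c_high: int, up_factors: tuple,
                 rng: np.random.Generator):
        super().__init__()
        self.up_factors = tuple(up_factors)
        self.low_conv = Conv3d(c_low, c_low, 1, rng=rng)
        self.low_bn = BatchNorm3d(c_low)
        self.gate_conv = Conv3d(c_high, c_low, 1, rng=rng)
        self.gate_bn = BatchNorm3d(c_low)
        kernel = tuple(4 if f == 2 else 1 for f in self.up_factors)
        pad = tuple(1 if f == 2 else 0 for f in self.up_factors)
        self.up = ConvTranspose3d(c_high, c_low, kernel, stride=self.up_factors,
                                  padding=pad, rng=rng)
        self.up_bn = BatchNorm3d(c_low)

    def forward(self, F1_low: Tensor, F2_high: Tensor) -> Tensor:
        F3 = relu(self.low_bn(self.low_conv(F1_low)))
        W1 = relu(self.gate_bn(self.gate_conv(global_avg_pool3d(F2_high))))
        F3 = F3 * W1
        F4 = self.up_bn(self.up(F2_high))
        if F4.shape != F3.shape:
            raise ShapeError(
                f"GAU upsampled high-level map has shape {F4.shape} but the "
                f"low-level path produced {F3.shape}")
        return F3 + F4


_COMBINE_MODES = ("parallel", "sequential_spatial_first", "sequential_channel_first")


def combine_attention(F1_low: Tensor, F2_high: Tensor, mode: str,
                      sse: SpatialSE, gau: GAU3d) -> Tensor:
    """Fuse spatial (sSE) and channel (GAU) attention in one of three ways.

    spatial-first applies sSE to the low-level map before the GAU; channel-
    first gates the GAU output spatially; parallel sums the two module
    outputs elementwise (both already carry C_L channels, so no extra
    projection is needed).
    """
    if mode == "sequential_spatial_first":
        return gau(sse(F1_low), F2_high)
    if mode == "sequential_channel_first":
        return sse(gau(F1_low, F2_high))
    if mode == "parallel":
        return sse(F1_low) + gau(F1_low, F2_high)
    raise ValueError(f"unknown combine mode {mode!r}; valid: {', '.join(_COMBINE_MODES)}")


class _AttentionFusion(Module):
    """Per-level decoder stage holding the sSE/GAU pair for one skip level."""

    def __init__(self, c_low: int, c_high: int, up_factors: tuple,
                 variant: str, rng: np.random.Generator):
        super().__init__()
        self.variant = variant
        self.gau = GAU3d(c_low, c_high, up_factors, rng=rng)
        if variant in SSE_VARIANTS:
            self.sse = SpatialSE(c_low, rng=rng)
        else:
            self.sse = None

    def forward(self, F1_low: Tensor, F2_high: Tensor) -> Tensor:
        if self.sse is None:
            return self.gau(F1_low, F2_high)
        return combine_attention(F1_low, F2_high, self.variant, self.sse, self.gau)


class _BaselineUp(Module):
    """Classic U-Net decoder stage: transposed conv, concat skip, conv block."""

    def __init__(self, c_low: int, c_high: int, up_factors: tuple,
                 rng: np.random.Generator):
        super().__init__()
        kernel = tuple(2 if f == 2 else 1 for f in up_factors)
        self.up = ConvTranspose3d(c_high, c_low, kernel, stride=up_factors,
                                  padding=(0, 0, 0), rng=rng)
        self.block = ConvBlock(2 * c_low, c_low, rng=rng)

    def forward(self, skip: Tensor, high: Tensor) -> Tensor:
        return self.block(concat([self.up(high), skip], axis=1))


class AttentionUNet3D(Module):
    """The full network; input ``(N, C_in, D, H, W)`` -> logits of the same
    spatial shape with one channel."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.encoder_channels
        f = config.pool_factors

        self.enc0 = ConvBlock(config.in_channels, ch[0], rng)
        for lvl in range(1, config.n_pool + 1):
            setattr(self, f"enc{lvl}", ConvBlock(ch[lvl - 1], ch[lvl], rng))

        variant = config.variant
        if variant in ("baseline_3dunet", "sse_only"):
            if variant == "sse_only":
                for lvl in range(config.n_pool + 1):
                    setattr(self, f"sse{lvl}", SpatialSE(ch[lvl], rng))
            for lvl in reversed(range(config.n_pool)):
                setattr(self, f"dec{lvl}", _BaselineUp(ch[lvl], ch[lvl + 1], f, rng))
        else:
            if variant in SSE_VARIANTS and config.sse_on_bottleneck:
                self.sse_bottleneck = SpatialSE(ch[-1], rng)
            for lvl in reversed(range(config.n_pool)):
                setattr(self, f"dec{lvl}",
                        _AttentionFusion(ch[lvl], ch[lvl + 1], f, variant, rng))

        self.head = Conv3d(ch[0], 1, 1, rng=rng)

    # ------------------------------------------------------------------
    def _check_divisible(self, spatial: tuple) -> None:
        need = self.config.downsampling
        bad = [f"axis {i} (size {s}, needs multiple of {n})"
               for i, (s, n) in enumerate(zip(spatial, need)) if s % n]
        if bad:
            raise ConfigurationError(
                "input spatial dims must be divisible by the total pooling "
                f"factor {need}: " + "; ".join(bad))

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self._check_divisible(x.shape[2:])
        cfg = self.config
        f = cfg.pool_factors
        feats = []
        h = x
        for lvl in range(cfg.n_pool + 1):
            if lvl > 0:
                h = max_pool3d(h, f)
            h = getattr(self, f"enc{lvl}")(h)
            if cfg.variant == "sse_only":
                h = getattr(self, f"sse{lvl}")(h)
            feats.append(h)

        h = feats[-1]
        if getattr(self, "sse_bottleneck", None) is not None:
            h = self.sse_bottleneck(h)
        for lvl in reversed(range(cfg.n_pool)):
            h = getattr(self, f"dec{lvl}")(feats[lvl], h)
        return self.head(h)


def build_network(config: NetworkConfig) -> AttentionUNet3D:
    return AttentionUNet3D(config)


# ---------------------------------------------------------------------------
# Self-describing checkpoints: weights + full NetworkConfig in one .npz.
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: AttentionUNet3D, extra: dict | None = None) -> None:
    meta = {"net_config": asdict(model.config)}
    if extra:
        meta.update(extra)
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[AttentionUNet3D, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = NetworkConfig(**meta["net_config"])
    model = build_network(config)
    model.load_state_dict(state)
    return model, meta
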