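"""Layer/module abstractions over the autograd engine.

Modules register parameters, buffers and submodules automatically through
attribute assignment (the familiar deep-learning convention), expose
``state_dict``/``load_state_dict`` for checkpointing, and carry a
training/eval flag that batch normalisation consults.
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, batch_norm3d, conv3d, conv_transpose3d)

__all__ = ["Parameter", "Module", "Conv3d", "ConvTranspose3d", "BatchNorm3d"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- train/eval --------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"state_dict missing entries: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
            p.grad = None
        for name, b in bufs.items():
            b[...] = np.asarray(state[name], dtype=b.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _triple(v) -> tuple:
    if np.isscalar(v):
        return (int(v),) * 3
    return tuple(int(x) for x in v)


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He initialisation (fan-in, gain for ReLU)."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    """Stride-1 3D convolution with zero padding (default 'same' for odd kernels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 padding=None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        k = _triple(kernel_size)
        if padding is None:
            padding = tuple(kk // 2 for kk in k)
        self.padding = _triple(padding)
        fan_in = in_channels * int(np.prod(k))
        self.weight = Parameter(kaiming_normal(rng, (out_channels, in_channels) + k, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride, padding=(0, 0, 0), bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        k = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = in_channels * int(np.prod(k))
        self.weight = Parameter(kaiming_normal(rng, (in_channels, out_channels) + k, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias,
                                stride=self.stride, padding=self.padding)


class BatchNorm3d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm3d(x, self.weight, self.bias,
                            self.running_mean, self.running_var,
                            training=self.training,
                            momentum=self.momentum, eps=self.eps)
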