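"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains volumetric convolutional networks on CPU, so the engine
implements exactly the operator set those networks need: elementwise
arithmetic with broadcasting, reductions, ReLU/sigmoid, channel
concatenation, 3D convolution (stride 1, zero padding), strided 3D
transposed convolution, max pooling and batch normalisation.  Convolutions
are evaluated as one BLAS matmul per kernel offset, which keeps peak memory
at a small multiple of the activation size while staying vectorised.

All data is float32.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` via an iterative topological sort, so arbitrarily
wired graphs (skip connections, gated branches) differentiate correctly.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "relu",
    "sigmoid",
    "concat",
    "conv3d",
    "conv_transpose3d",
    "max_pool3d",
    "batch_norm3d",
    "global_avg_pool3d",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_f32(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype != np.float32:
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- backprop ----------------------------------------------------------
    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without an explicit gradient "
                                   "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(_as_f32(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph to bound memory
                if node is not self:
                    node.grad = None
                    node._backward = None
                    node._parents = ()

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accum(_unbroadcast(grad, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(grad):
            if a.requires_grad:
                a._accum(-grad)

        return Tensor._result(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accum(_unbroadcast(grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accum(_unbroadcast(grad / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-grad * a.data / (b.data * b.data), b.data.shape))

        return Tensor._result(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims, dtype=np.float32)

        def backward(grad):
            if not a.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

        return Tensor._result(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(grad):
        if x.requires_grad:
            x._accum(grad * mask)

    return Tensor._result(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    s[~pos] = ex / (1.0 + ex)

    def backward(grad):
        if x.requires_grad:
            x._accum(grad * s * (1.0 - s))

    return Tensor._result(s, (x,), backward)


def concat(tensors: list, axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(grad[tuple(sl)])

    return Tensor._result(data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Convolution family.  x: (N, C, D, H, W).  Stride-1 conv with zero padding;
# strided transposed conv.  Weight layouts follow the common deep-learning
# convention: conv (C_out, C_in, kd, kh, kw), transposed (C_in, C_out, ...).
# ---------------------------------------------------------------------------

def _offsets(kd, kh, kw):
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                yield i, j, k


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: tuple = (0, 0, 0)) -> Tensor:
    N, C, D, H, W = x.data.shape
    Co, Ci, kd, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight expects {Ci}")
    pd, ph, pw = padding
    Do, Ho, Wo = D + 2 * pd - kd + 1, H + 2 * ph - kh + 1, W + 2 * pw - kw + 1
    if min(Do, Ho, Wo) < 1:
        raise ValueError("conv3d: kernel larger than padded input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    L = Do * Ho * Wo
    out = np.zeros((N, Co, L), dtype=np.float32)
    for i, j, k in _offsets(kd, kh, kw):
        xs = np.ascontiguousarray(xp[:, :, i:i + Do, j:j + Ho, k:k + Wo]).reshape(N, C, L)
        out += np.matmul(w.data[:, :, i, j, k], xs)
    out = out.reshape(N, Co, Do, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, Co, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        go = grad.reshape(N, Co, L)
        if b is not None and b.requires_grad:
            b._accum(go.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for i, j, k in _offsets(kd, kh, kw):
                xs = np.ascontiguousarray(
                    xp[:, :, i:i + Do, j:j + Ho, k:k + Wo]).reshape(N, C, L)
                gw[:, :, i, j, k] = np.tensordot(go, xs, axes=([0, 2], [0, 2]))
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i, j, k in _offsets(kd, kh, kw):
                contrib = np.matmul(w.data[:, :, i, j, k].T, go).reshape(N, C, Do, Ho, Wo)
                gxp[:, :, i:i + Do, j:j + Ho, k:k + Wo] += contrib
            x._accum(gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W])

    return Tensor._result(out, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: tuple = (1, 1, 1), padding: tuple = (0, 0, 0)) -> Tensor:
    N, C, D, H, W = x.data.shape
    Ci, Co, kd, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv_transpose3d channel mismatch: input {C}, weight expects {Ci}")
    sd, sh, sw = stride
    pd, ph, pw = padding
    Df, Hf, Wf = (D - 1) * sd + kd, (H - 1) * sh + kh, (W - 1) * sw + kw
    L = D * H * W
    xr = x.data.reshape(N, C, L)
    full = np.zeros((N, Co, Df, Hf, Wf), dtype=np.float32)
    for i, j, k in _offsets(kd, kh, kw):
        contrib = np.matmul(w.data[:, :, i, j, k].T, xr).reshape(N, Co, D, H, W)
        full[:, :,
             i:i + (D - 1) * sd + 1:sd,
             j:j + (H - 1) * sh + 1:sh,
             k:k + (W - 1) * sw + 1:sw] += contrib
    out = full[:, :, pd:Df - pd, ph:Hf - ph, pw:Wf - pw]
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1, 1)
    else:
        out = np.ascontiguousarray(out)

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        gfull = np.zeros((N, Co, Df, Hf, Wf), dtype=np.float32)
        gfull[:, :, pd:Df - pd, ph:Hf - ph, pw:Wf - pw] = grad
        if b is not None and b.requires_grad:
            b._accum(grad.sum(axis=(0, 2, 3, 4)))
        gx = np.zeros((N, C, L), dtype=np.float32) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for i, j, k in _offsets(kd, kh, kw):
            gs = np.ascontiguousarray(
                gfull[:, :,
                      i:i + (D - 1) * sd + 1:sd,
                      j:j + (H - 1) * sh + 1:sh,
                      k:k + (W - 1) * sw + 1:sw]).reshape(N, Co, L)
            if gx is not None:
                gx += np.matmul(w.data[:, :, i, j, k], gs)
            if gw is not None:
                gw[:, :, i, j, k] = np.tensordot(xr, gs, axes=([0, 2], [0, 2]))
        if gx is not None:
            x._accum(gx.reshape(N, C, D, H, W))
        if gw is not None:
            w._accum(gw)

    return Tensor._result(out, parents, backward)


def max_pool3d(x: Tensor, factors: tuple = (2, 2, 2)) -> Tensor:
    N, C, D, H, W = x.data.shape
    fd, fh, fw = factors
    if D % fd or H % fh or W % fw:
        raise ValueError(f"max_pool3d: shape {(D, H, W)} not divisible by {factors}")
    Do, Ho, Wo = D // fd, H // fh, W // fw
    xv = (x.data.reshape(N, C, Do, fd, Ho, fh, Wo, fw)
          .transpose(0, 1, 2, 4, 6, 3, 5, 7)
          .reshape(N, C, Do, Ho, Wo, fd * fh * fw))
    idx = xv.argmax(axis=-1)
    out = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]

    def backward(grad):
        if not x.requires_grad:
            return
        gv = np.zeros((N, C, Do, Ho, Wo, fd * fh * fw), dtype=np.float32)
        np.put_along_axis(gv, idx[..., None], grad[..., None], axis=-1)
        gx = (gv.reshape(N, C, Do, Ho, Wo, fd, fh, fw)
              .transpose(0, 1, 2, 5, 3, 6, 4, 7)
              .reshape(N, C, D, H, W))
        x._accum(gx)

    return Tensor._result(out, (x,), backward)


def global_avg_pool3d(x: Tensor) -> Tensor:
    N, C, D, H, W = x.data.shape
    nvox = D * H * W
    out = x.data.mean(axis=(2, 3, 4), keepdims=True)

    def backward(grad):
        if x.requires_grad:
            x._accum(np.broadcast_to(grad / nvox, x.data.shape).astype(np.float32))

    return Tensor._result(out, (x,), backward)


def batch_norm3d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, D, H, W).

    ``running_mean``/``running_var`` are plain arrays owned by the calling
    module and are updated in place during training forward passes.
    """
    N, C, D, H, W = x.data.shape
    axes = (0, 2, 3, 4)
    n = N * D * H * W
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        unbiased = var * (n / max(n - 1, 1))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    shape = (1, C, 1, 1, 1)
    xhat = (x.data - mean.reshape(shape)) * invstd.reshape(shape)
    out = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)

    def backward(grad):
        if gamma.requires_grad:
            gamma._accum((grad * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(grad.sum(axis=axes))
        if x.requires_grad:
            g = gamma.data.reshape(shape) * invstd.reshape(shape)
            if training:
                gsum = grad.sum(axis=axes).reshape(shape)
                gxsum = (grad * xhat).sum(axis=axes).reshape(shape)
                gx = g * (grad - gsum / n - xhat * gxsum / n)
            else:
                gx = g * grad
            x._accum(gx.astype(np.float32))

    return Tensor._result(out, (x, gamma, beta), backward)
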