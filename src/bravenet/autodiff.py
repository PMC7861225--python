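"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the operations the segmentation networks
need: 3-D convolution (stride 1, "same" padding, odd kernels), batch
normalization, ReLU / sigmoid, 2x2x2 max- and average-pooling,
nearest-neighbour up-sampling, channel concatenation, dropout, and the
elementwise/reduction arithmetic used by the soft-Dice loss.  Tensors
record their parents and a backward closure; `Tensor.backward()` runs a
topological sweep accumulating gradients.

All spatial tensors are laid out as (N, C, X, Y, Z).  The engine is
dtype-agnostic: it computes in whatever dtype the arrays carry, which
lets tests run gradient checks in float64 while training uses float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "batch_norm",
    "relu",
    "sigmoid",
    "max_pool2",
    "avg_pool2",
    "upsample_nearest",
    "concat",
    "dropout",
    "Adam",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic (shapes equal, or scalar operands) -----

    def __add__(self, other):
        if not isinstance(other, Tensor):
            out = Tensor(self.data + other, parents=(self,))
            out._backward = lambda g, a=self: a._accumulate(_unbroadcast(g, a.shape))
            return out
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g, a=self: a._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Tensor):
            c = np.asarray(other)
            out = Tensor(self.data * c, parents=(self,))
            out._backward = lambda g, a=self: a._accumulate(
                _unbroadcast(g * c, a.shape)
            )
            return out
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor):
            return self * (1.0 / np.asarray(other))
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(
                    _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        out = Tensor(np.asarray(other) / self.data, parents=(self,))
        out._backward = lambda g, a=self, c=np.asarray(other): a._accumulate(
            _unbroadcast(-g * c / (a.data * a.data), a.shape)
        )
        return out

    def square(self):
        out = Tensor(self.data * self.data, parents=(self,))
        out._backward = lambda g, a=self: a._accumulate(2.0 * g * a.data)
        return out

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g, a=self: a._accumulate(
            np.broadcast_to(g, a.shape)
        )
        return out


def _unbroadcast(g, shape):
    """Reduce gradient g back to `shape` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------
# convolution


def _conv3d_raw(x, w):
    """'Same'-padded stride-1 3-D cross-correlation of x (N,C,X,Y,Z)
    with w (Cout,Cin,kx,ky,kz); odd kernels only."""
    kx, ky, kz = w.shape[2:]
    px, py, pz = kx // 2, ky // 2, kz // 2
    N, C, X, Y, Z = x.shape
    if (px, py, pz) == (0, 0, 0):
        out = np.tensordot(w[:, :, 0, 0, 0], x, axes=([1], [1]))
        return np.ascontiguousarray(np.moveaxis(out, 0, 1))
    xp = np.pad(x, ((0, 0), (0, 0), (px, px), (py, py), (pz, pz)))
    out = np.zeros((w.shape[0], N, X, Y, Z), dtype=x.dtype)
    for a in range(kx):
        for b in range(ky):
            for c in range(kz):
                xs = xp[:, :, a : a + X, b : b + Y, c : c + Z]
                out += np.tensordot(w[:, :, a, b, c], xs, axes=([1], [1]))
    return np.ascontiguousarray(np.moveaxis(out, 0, 1))


def _conv3d_dw(x, dout, kshape):
    """Gradient w.r.t. the kernel for the same-padded convolution."""
    kx, ky, kz = kshape
    px, py, pz = kx // 2, ky // 2, kz // 2
    N, C, X, Y, Z = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (px, px), (py, py), (pz, pz)))
    cout = dout.shape[1]
    dw = np.empty((cout, C, kx, ky, kz), dtype=x.dtype)
    for a in range(kx):
        for b in range(ky):
            for c in range(kz):
                xs = xp[:, :, a : a + X, b : b + Y, c : c + Z]
                dw[:, :, a, b, c] = np.tensordot(
                    dout, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                )
    return dw


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """3-D convolution, stride 1, same padding. x: (N,C,X,Y,Z)."""
    out_data = _conv3d_raw(x.data, w.data)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def bwd(g, x=x, w=w, b=b):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            w._accumulate(_conv3d_dw(x.data, g, w.data.shape[2:]))
        if x.requires_grad:
            # transposed conv = same-padded conv with flipped, swapped kernel
            wt = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].swapaxes(0, 1)
            )
            x._accumulate(_conv3d_raw(g, wt))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------
# batch normalization


class BatchNormState:
    """Running statistics for one batch-norm layer (not trainable)."""

    def __init__(self, channels, dtype=np.float32, momentum=0.9, eps=1e-5):
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               state: BatchNormState, train: bool) -> Tensor:
    """Per-channel batch normalization over (N, X, Y, Z)."""
    axes = (0, 2, 3, 4)
    eps = state.eps
    if train:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = state.momentum
        state.running_mean = m * state.running_mean + (1 - m) * mean.astype(
            state.running_mean.dtype
        )
        state.running_var = m * state.running_var + (1 - m) * var.astype(
            state.running_var.dtype
        )
    else:
        mean = state.running_mean.astype(x.dtype)
        var = state.running_var.astype(x.dtype)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1, 1)) * inv_std.reshape(
        1, -1, 1, 1, 1
    )
    out_data = gamma.data.reshape(1, -1, 1, 1, 1) * xhat + beta.data.reshape(
        1, -1, 1, 1, 1
    )
    out = Tensor(out_data, parents=(x, gamma, beta))

    def bwd(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv_std=inv_std,
            train=train):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if x.requires_grad:
            gm = gamma.data.reshape(1, -1, 1, 1, 1)
            istd = inv_std.reshape(1, -1, 1, 1, 1)
            if train:
                n = g.shape[0] * g.shape[2] * g.shape[3] * g.shape[4]
                gxh = g * gm
                dx = istd * (
                    gxh
                    - gxh.mean(axis=axes, keepdims=True)
                    - xhat * (gxh * xhat).mean(axis=axes, keepdims=True)
                )
                del n
            else:
                dx = g * gm * istd
            x._accumulate(dx)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------
# activations, pooling, resampling


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), parents=(x,))
    out._backward = lambda g, x=x, mask=mask: x._accumulate(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    with np.errstate(over="ignore"):  # exp overflow saturates to 0/1
        s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g, x=x, s=s: x._accumulate(g * s * (1.0 - s))
    return out


def _blockify(a):
    """(N,C,X,Y,Z) -> (N,C,X/2,Y/2,Z/2,8) view-copy of 2x2x2 blocks."""
    N, C, X, Y, Z = a.shape
    r = a.reshape(N, C, X // 2, 2, Y // 2, 2, Z // 2, 2)
    return r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        N, C, X // 2, Y // 2, Z // 2, 8
    )


def _unblockify(blocks, shape):
    N, C, X, Y, Z = shape
    r = blocks.reshape(N, C, X // 2, Y // 2, Z // 2, 2, 2, 2)
    return r.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(shape)


def _check_even(shape):
    if any(s % 2 for s in shape[2:]):
        raise ValueError(
            f"2x2x2 pooling requires even spatial dimensions, got {shape[2:]}"
        )


def max_pool2(x: Tensor) -> Tensor:
    """2x2x2 max-pooling with stride 2."""
    _check_even(x.shape)
    blocks = _blockify(x.data)
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, parents=(x,))

    def bwd(g, x=x, idx=idx):
        gb = np.zeros(idx.shape + (8,), dtype=g.dtype)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        x._accumulate(_unblockify(gb, x.shape))

    out._backward = bwd
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x2x2 average-pooling with stride 2."""
    _check_even(x.shape)
    out = Tensor(_blockify(x.data).mean(axis=-1), parents=(x,))

    def bwd(g, x=x):
        gb = np.repeat(g[..., None] / 8.0, 8, axis=-1)
        x._accumulate(_unblockify(gb, x.shape))

    out._backward = bwd
    return out


def upsample_nearest(x: Tensor, factor) -> Tensor:
    """Nearest-neighbour up-sampling by integer factors per spatial axis."""
    fx, fy, fz = factor
    d = np.repeat(np.repeat(np.repeat(x.data, fx, 2), fy, 3), fz, 4)
    out = Tensor(d, parents=(x,))

    def bwd(g, x=x):
        N, C, X, Y, Z = x.shape
        gr = g.reshape(N, C, X, fx, Y, fy, Z, fz)
        x._accumulate(gr.sum(axis=(3, 5, 7)))

    out._backward = bwd
    return out


def concat(tensors, axis=1) -> Tensor:
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g, tensors=tuple(tensors), splits=splits, axis=axis):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(gpart)

    out._backward = bwd
    return out


def sum_except_batch(x: Tensor) -> Tensor:
    """Sum over all axes but the first, giving a (N,) tensor."""
    axes = tuple(range(1, x.data.ndim))
    out = Tensor(x.data.sum(axis=axes), parents=(x,))

    def bwd(g, x=x):
        shape = (x.shape[0],) + (1,) * (len(x.shape) - 1)
        x._accumulate(np.broadcast_to(g.reshape(shape), x.shape))

    out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    out = Tensor(x.data * keep, parents=(x,))
    out._backward = lambda g, x=x, keep=keep: x._accumulate(g * keep)
    return out


# ---------------------------------------------------------------------
# optimizer


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )
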