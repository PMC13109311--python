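"""Minimal tape-based reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a 1-D convolutional / recurrent / attention
regressor: broadcasting arithmetic, batched matmul, shape ops, pointwise
nonlinearities, softmax, 1-D convolution and max-pooling, and an Adam
optimizer.  Everything is float64 and seeded explicitly; there is no
device abstraction and no graph caching — gradients are exact, not fast.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "conv1d", "max_pool1d", "Adam", "no_grad"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference mode): no graph, no gradients."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward):
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED[-1] and any(
            p.requires_grad for p in parents
        )
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative post-order topological sort (no recursion: deep tapes
        # from recurrent loops would overflow the stack, and a recursive
        # closure would cycle-reference the whole tape)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self.data @ other.data

        def bw(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return self._make(out, (self, other), bw)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), bw)

    def __getitem__(self, key):
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key)
        )

        def bw(g):
            full = np.zeros_like(self.data)
            if basic:  # views never alias in a single getitem
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._accum(full)

        return self._make(self.data[key], (self,), bw)

    # -- reductions & nonlinearities ----------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)


def concat(tensors: list, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED[-1] and any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (max detached)."""
    shifted = x + (-np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-mode 1-D convolution (cross-correlation) with stride 1.

    x: (N, C_in, L); w: (C_out, C_in, K); b: (C_out,) -> (N, C_out, L-K+1).
    """
    N, C, L = x.data.shape
    O, _, K = w.data.shape
    cols = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)
    )  # (N, C, Lo, K)
    # contract over (C, K): BLAS-backed tensordot beats the einsum loop here
    out = np.tensordot(cols, w.data, axes=([1, 3], [1, 2]))  # (N, Lo, O)
    out = out.transpose(0, 2, 1) + b.data[None, :, None]

    def bw(g):
        # g: (N, O, Lo)
        w._accum(np.tensordot(g, cols, axes=([0, 2], [0, 2])))  # (O, C, K)
        b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            Lo = g.shape[2]
            gw = np.tensordot(g, w.data, axes=(1, 0))  # (N, Lo, C, K)
            for k in range(K):
                gx[:, :, k:k + Lo] += gw[:, :, :, k].transpose(0, 2, 1)
            x._accum(gx)

    out_t = Tensor(out)
    out_t.requires_grad = _GRAD_ENABLED[-1] and (
        x.requires_grad or w.requires_grad or b.requires_grad
    )
    if out_t.requires_grad:
        out_t._parents = (x, w, b)
        out_t._backward = bw
    return out_t


def max_pool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling along the last axis (truncates remainder)."""
    N, C, L = x.data.shape
    Lo = L // size
    trimmed = x.data[:, :, : Lo * size].reshape(N, C, Lo, size)
    arg = trimmed.argmax(axis=3)
    out = trimmed.max(axis=3)

    def bw(g):
        gx = np.zeros((N, C, Lo, size))
        n_i, c_i, l_i = np.meshgrid(
            np.arange(N), np.arange(C), np.arange(Lo), indexing="ij"
        )
        gx[n_i, c_i, l_i, arg] = g
        full = np.zeros_like(x.data)
        full[:, :, : Lo * size] = gx.reshape(N, C, Lo * size)
        x._accum(full)

    out_t = Tensor(out)
    out_t.requires_grad = _GRAD_ENABLED[-1] and x.requires_grad
    if out_t.requires_grad:
        out_t._parents = (x,)
        out_t._backward = bw
    return out_t


class Adam:
    """Adaptive-moment-estimation optimizer over a parameter list."""

    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
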