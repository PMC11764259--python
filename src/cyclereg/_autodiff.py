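"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the style of the classic define-by-run
frameworks: every operation on :class:`Tensor` records its inputs and a
closure computing the vector-Jacobian product, and :meth:`Tensor.backward`
walks the graph in reverse topological order.  Only the operations needed
by the registration network, the spatial transformer and the loss terms
are provided; everything is float64 so finite-difference gradient checks
are sharp.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = ["Tensor", "Module", "Adam", "as_tensor", "concatenate", "stack", "conv3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, fn: upstream grad -> grad contribution)
        self._parents: list = []

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, parents) -> "Tensor":
        parents = [(p, fn) for p, fn in parents if p.requires_grad or p._parents]
        out = Tensor(data, requires_grad=bool(parents))
        out._parents = parents
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward pass ----------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)
        # iterative DFS topological sort (graphs can be thousands deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor._make(a.data + b.data, [
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ])

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor._make(a.data * b.data, [
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor._make(a.data / b.data, [
            (a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)),
        ])

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, k):
        if not np.isscalar(k):
            raise TypeError("only scalar exponents are supported")
        a = self
        return Tensor._make(a.data ** k, [
            (a, lambda g: g * k * a.data ** (k - 1)),
        ])

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul requires ndim >= 2 operands")
        out = a.data @ b.data
        return Tensor._make(out, [
            (a, lambda g: _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)),
            (b, lambda g: _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)),
        ])

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, [(self, lambda g: g * 0.5 / out)])

    def abs(self):
        # subgradient 0 at the kink
        return Tensor._make(np.abs(self.data), [(self, lambda g: g * np.sign(self.data))])

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, [(self, lambda g: g * (1.0 - out ** 2))])

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * factor, [(self, lambda g: g * factor)])

    def gelu(self):
        from scipy.special import erf

        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x ** 2) / math.sqrt(2.0 * math.pi)
        return Tensor._make(x * cdf, [(self, lambda g: g * (cdf + x * pdf))])

    def clip(self, lo, hi):
        out = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(out, [(self, lambda g: g * mask)])

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(i % a.ndim for i in ax)
                g = np.expand_dims(g, ax)
            return np.broadcast_to(g, a.data.shape).copy()

        return Tensor._make(out, [(a, back)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i % self.ndim] for i in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(a.data.reshape(shape), [
            (a, lambda g: g.reshape(a.data.shape)),
        ])

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        a = self
        return Tensor._make(a.data.transpose(axes), [
            (a, lambda g: g.transpose(inv)),
        ])

    def __getitem__(self, idx):
        a = self
        out = a.data[idx]

        def back(g):
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            return acc

        return Tensor._make(out, [(a, back)])

    def pad(self, pad_width):
        a = self
        out = np.pad(a.data, pad_width)
        slc = tuple(slice(p[0], p[0] + s) for p, s in zip(pad_width, a.data.shape))
        return Tensor._make(out, [(a, lambda g: g[slc])])

    def roll(self, shift, axis):
        a = self
        return Tensor._make(np.roll(a.data, shift, axis=axis), [
            (a, lambda g: np.roll(g, tuple(-s for s in shift) if isinstance(shift, tuple) else -shift, axis=axis)),
        ])

    # -- composites ----------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        n = t.data.shape[axis]
        slc = [slice(None)] * out.ndim
        slc[axis] = slice(offset, offset + n)
        parents.append((t, (lambda s: (lambda g: g[tuple(s)]))(list(slc))))
        offset += n
    return Tensor._make(out, parents)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)
    parents = []
    for i, t in enumerate(tensors):
        parents.append((t, (lambda j: (lambda g: np.take(g, j, axis=axis)))(i)))
    return Tensor._make(out, parents)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 1,
           pad_mode: str = "constant") -> Tensor:
    """3D cross-correlation, stride 1.

    x: (Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,).
    pad_mode "edge" replicates the border (keeps constant inputs constant).
    """
    x, w = as_tensor(x), as_tensor(w)
    cin, D, H, W = x.shape
    cout, cin2, k, _, _ = w.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, kernel expects {cin2}")
    xp = np.pad(x.data, ((0, 0),) + ((padding, padding),) * 3, mode=pad_mode)
    cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    # cols: (Cin, D, H, W, k, k, k) -> (D*H*W, Cin*k^3)
    cols2 = cols.transpose(1, 2, 3, 0, 4, 5, 6).reshape(D * H * W, cin * k ** 3)
    wm = w.data.reshape(cout, cin * k ** 3)
    out = cols2 @ wm.T
    out = out.reshape(D, H, W, cout).transpose(3, 0, 1, 2)

    def back_x(g):
        g2 = g.transpose(1, 2, 3, 0).reshape(D * H * W, cout)
        gcols = (g2 @ wm).reshape(D, H, W, cin, k, k, k)
        gxp = np.zeros_like(xp)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    gxp[:, a:a + D, bb:bb + H, c:c + W] += np.moveaxis(gcols[:, :, :, :, a, bb, c], -1, 0)
        if padding:
            if pad_mode == "edge":
                # fold padded-cell gradients back onto the replicated border
                for ax in (1, 2, 3):
                    lead = [slice(None)] * 4
                    edge = [slice(None)] * 4
                    lead[ax], edge[ax] = slice(0, padding), slice(padding, padding + 1)
                    gxp[tuple(edge)] += gxp[tuple(lead)].sum(axis=ax, keepdims=True)
                    lead[ax] = slice(-padding, None)
                    edge[ax] = slice(-padding - 1, -padding)
                    gxp[tuple(edge)] += gxp[tuple(lead)].sum(axis=ax, keepdims=True)
            return gxp[:, padding:-padding, padding:-padding, padding:-padding]
        return gxp

    def back_w(g):
        g2 = g.transpose(1, 2, 3, 0).reshape(D * H * W, cout)
        return (g2.T @ cols2).reshape(w.data.shape)

    parents = [(x, back_x), (w, back_w)]
    result = Tensor._make(out, parents)
    if b is not None:
        result = result + as_tensor(b).reshape(cout, 1, 1, 1)
    return result


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
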