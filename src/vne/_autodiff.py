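"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the virtual-native-enhancement networks
need — 3×3 same-padded convolution (im2col), 2×2 average pooling, nearest
×2 upsampling, leaky ReLU, channel concatenation and elementwise
arithmetic/reductions — for NCHW float32 batches.  Gradients are
accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "conv2d",
    "leaky_relu",
    "avg_pool2",
    "upsample2",
    "concat",
    "add",
    "sub",
    "mul_const",
    "square",
    "absolute",
    "mean",
    "Adam",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray, fresh: bool = False) -> None:
        """Add ``g`` to the gradient; ``fresh`` marks arrays safe to adopt."""
        if self.grad is None:
            if fresh and g.dtype == np.float32 and g.flags["OWNDATA"]:
                self.grad = g
            else:
                self.grad = g.astype(np.float32)
        else:
            self.grad += g


def _unary(x: Tensor, out_data: np.ndarray, grad_fn) -> Tensor:
    # every grad_fn below allocates its output, so adoption is safe
    def backward(g):
        if x.requires_grad:
            x._accumulate(grad_fn(g), fresh=True)

    return Tensor(out_data, parents=(x,), backward=backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 convolution; x (N,C,H,W), w (O,C,kh,kw), b (O,)."""
    n, c, h, wdt = x.data.shape
    o, ci, kh, kw = w.data.shape
    assert ci == c, f"channel mismatch: input {c}, weight {ci}"
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * wdt, c * kh * kw
    )
    wmat = w.data.reshape(o, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(n, h, wdt, o).transpose(0, 3, 1, 2)

    def backward(g):
        g_rows = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wdt, o)
        if w.requires_grad:
            w._accumulate((g_rows.T @ cols).reshape(o, c, kh, kw), fresh=True)
        if b is not None and b.requires_grad:
            b._accumulate(g_rows.sum(axis=0), fresh=True)
        if x.requires_grad:
            dcols = (g_rows @ wmat).reshape(n, h, wdt, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + h, j : j + wdt] += dcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            x._accumulate(np.ascontiguousarray(dxp[:, :, ph : ph + h, pw : pw + wdt]),
                          fresh=True)

    return Tensor(out, parents=(x, w) + ((b,) if b is not None else ()), backward=backward)


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, alpha * x.data)
    return _unary(x, out, lambda g: np.where(pos, g, alpha * g))


def avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def grad_fn(g):
        return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25

    return _unary(x, out, grad_fn)


def upsample2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def grad_fn(g):
        return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

    return _unary(x, out, grad_fn)


def concat(xs: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in xs], axis=1)
    sizes = [t.data.shape[1] for t in xs]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(g[:, lo:hi])

    return Tensor(out, parents=tuple(xs), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(a.data + b.data, parents=(a, b), backward=backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(-g)

    return Tensor(a.data - b.data, parents=(a, b), backward=backward)


def mul_const(x: Tensor, k: float) -> Tensor:
    return _unary(x, x.data * k, lambda g: g * k)


def square(x: Tensor) -> Tensor:
    return _unary(x, x.data**2, lambda g: 2.0 * x.data * g)


def absolute(x: Tensor) -> Tensor:
    s = np.sign(x.data)
    return _unary(x, np.abs(x.data), lambda g: g * s)


def mean(x: Tensor) -> Tensor:
    inv = 1.0 / x.data.size
    return _unary(x, np.mean(x.data), lambda g: np.full_like(x.data, float(g) * inv))


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bias1 = 1.0 - self.b1**self.t
        bias2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
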