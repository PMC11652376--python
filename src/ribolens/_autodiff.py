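"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for an encoder transformer: broadcast-aware
elementwise ops, (batched) matmul, reductions, softmax / log-softmax,
embedding gather, and a dedicated rotary-position op whose backward is the
inverse rotation. Gradients accumulate into ``Tensor.grad`` on ``backward()``
via a topological sweep.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Optional, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_sink")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> np.ndarray:
        return self.data

    # -- graph plumbing ------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() only on scalars")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._grad_sink = grads  # type: ignore[attr-defined]
                node._backward(g)
                del node._grad_sink
            else:
                node.grad = g if node.grad is None else node.grad + g

        # Op-output tensors and their backward closures form reference
        # cycles; break them now that gradients have flowed so the graph
        # (and its large intermediate arrays) is freed immediately.
        for node in topo:
            node._backward = None
            node._parents = ()

    # closure helper used by op backwards
    @staticmethod
    def _accum(sink: dict, t: "Tensor", g: np.ndarray) -> None:
        if not t.requires_grad:
            return
        if t._backward is None and not t._parents:  # leaf
            t.grad = g if t.grad is None else t.grad + g
        else:
            key = id(t)
            sink[key] = g if key not in sink else sink[key] + g

    # -- ops -----------------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            sink = out._grad_sink
            Tensor._accum(sink, a, _unbroadcast(g, a.shape))
            Tensor._accum(sink, b, _unbroadcast(g, b.shape))

        out = self._make(self.data + other.data, (self, other), bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            Tensor._accum(out._grad_sink, a, -g)

        out = self._make(-self.data, (self,), bw)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            sink = out._grad_sink
            Tensor._accum(sink, a, _unbroadcast(g * b.data, a.shape))
            Tensor._accum(sink, b, _unbroadcast(g * a.data, b.shape))

        out = self._make(self.data * other.data, (self, other), bw)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            sink = out._grad_sink
            Tensor._accum(sink, a, _unbroadcast(g / b.data, a.shape))
            Tensor._accum(
                sink, b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
            )

        out = self._make(self.data / other.data, (self, other), bw)
        return out

    def __pow__(self, exponent: float):
        def bw(g, a=self, e=exponent):
            Tensor._accum(
                out._grad_sink, a, g * e * np.power(a.data, e - 1)
            )

        out = self._make(np.power(self.data, exponent), (self,), bw)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            sink = out._grad_sink
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            Tensor._accum(sink, a, _unbroadcast(ga, a.shape))
            Tensor._accum(sink, b, _unbroadcast(gb, b.shape))

        out = self._make(np.matmul(self.data, other.data), (self, other), bw)
        return out

    __matmul__ = matmul

    def exp(self):
        y = np.exp(self.data)

        def bw(g, a=self, y=y):
            Tensor._accum(out._grad_sink, a, g * y)

        out = self._make(y, (self,), bw)
        return out

    def log(self):
        def bw(g, a=self):
            Tensor._accum(out._grad_sink, a, g / a.data)

        out = self._make(np.log(self.data), (self,), bw)
        return out

    def tanh(self):
        y = np.tanh(self.data)

        def bw(g, a=self, y=y):
            Tensor._accum(out._grad_sink, a, g * (1 - y * y))

        out = self._make(y, (self,), bw)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accum(out._grad_sink, a, np.broadcast_to(g, a.shape).copy())

        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        def bw(g, a=self):
            Tensor._accum(out._grad_sink, a, g.reshape(a.shape))

        out = self._make(self.data.reshape(*shape), (self,), bw)
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g, a=self, inv=inv):
            Tensor._accum(out._grad_sink, a, g.transpose(*inv))

        out = self._make(self.data.transpose(*axes), (self,), bw)
        return out

    def __getitem__(self, idx):
        def bw(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            Tensor._accum(out._grad_sink, a, full)

        out = self._make(self.data[idx], (self,), bw)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g, a=self, y=y, axis=axis):
            dot = (g * y).sum(axis=axis, keepdims=True)
            Tensor._accum(out._grad_sink, a, y * (g - dot))

        out = self._make(y, (self,), bw)
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        x = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
        y = x - lse

        def bw(g, a=self, y=y, axis=axis):
            Tensor._accum(
                out._grad_sink,
                a,
                g - np.exp(y) * g.sum(axis=axis, keepdims=True),
            )

        out = self._make(y, (self,), bw)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: Optional[np.random.Generator] = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather with scatter-add backward."""
    ids = np.asarray(ids)

    def bw(g, t=table, ids=ids):
        full = np.zeros_like(t.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
        Tensor._accum(out._grad_sink, t, full)

    out = table._make(table.data[ids], (table,), bw)
    return out


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """tanh-approximation GELU as a single fused node."""
    d = x.data
    inner = _GELU_C * (d + 0.044715 * (d * d * d))  # d**3 spelt out: np.power
    t = np.tanh(inner)  # with scalar exponents is slow on some BLAS builds
    y = 0.5 * d * (1.0 + t)

    def bw(g, a=x, d=d, t=t):
        sech2 = 1.0 - t * t
        dydx = 0.5 * (1.0 + t) + 0.5 * d * sech2 * _GELU_C * (
            1.0 + 3 * 0.044715 * d * d
        )
        Tensor._accum(out._grad_sink, a, g * dydx)

    out = x._make(y, (x,), bw)
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis, fused forward/backward."""
    d = x.data
    mu = d.mean(axis=-1, keepdims=True)
    xc = d - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat * gain.data + bias.data

    def bw(g, a=x, gn=gain, bs=bias, xhat=xhat, inv=inv):
        sink = out._grad_sink
        n = xhat.shape[-1]
        red = tuple(range(xhat.ndim - 1))
        Tensor._accum(sink, gn, _unbroadcast(g * xhat, gn.shape))
        Tensor._accum(sink, bs, _unbroadcast(g, bs.shape))
        gx = g * gn.data
        gx = inv * (
            gx
            - gx.mean(axis=-1, keepdims=True)
            - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
        )
        Tensor._accum(sink, a, gx)

    out = x._make(y, (x, gain, bias), bw)
    return out


def rope(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
    """Rotary position embedding on the last axis (half-split convention).

    ``cos``/``sin`` have shape broadcastable to x[..., :d/2]. The map is an
    orthogonal rotation, so the backward pass applies the inverse rotation.
    """
    d = x.shape[-1]
    h = d // 2
    x1, x2 = x.data[..., :h], x.data[..., h:]
    y = np.concatenate([x1 * cos - x2 * sin, x2 * cos + x1 * sin], axis=-1)

    def bw(g, a=x, cos=cos, sin=sin, h=h):
        g1, g2 = g[..., :h], g[..., h:]
        gx = np.concatenate([g1 * cos + g2 * sin, g2 * cos - g1 * sin], axis=-1)
        Tensor._accum(out._grad_sink, a, gx)

    out = x._make(y, (x,), bw)
    return out


def linear(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Fused affine map on the last axis: x @ w (+ b).

    Collapses leading axes into one GEMM, which is markedly faster than a
    batched matmul for (B, L, D) activations.
    """
    xd = x.data
    lead = xd.shape[:-1]
    x2 = xd.reshape(-1, xd.shape[-1])
    y2 = x2 @ w.data
    if b is not None:
        y2 = y2 + b.data
    parents = (x, w) if b is None else (x, w, b)

    def bw(g, a=x, w=w, b=b, x2=x2, lead=lead):
        sink = out._grad_sink
        g2 = g.reshape(-1, g.shape[-1])
        Tensor._accum(sink, a, (g2 @ w.data.T).reshape(a.data.shape))
        Tensor._accum(sink, w, x2.T @ g2)
        if b is not None:
            Tensor._accum(sink, b, g2.sum(axis=0))

    out = x._make(y2.reshape(*lead, -1), parents, bw)
    return out


def attention(
    q: Tensor, k: Tensor, v: Tensor, addmask: np.ndarray, scale: float
) -> tuple[Tensor, np.ndarray]:
    """Fused scaled-dot-product attention.

    Inputs are (B, H, L, hd); ``addmask`` broadcasts onto the (B, H, L, L)
    logits (large negative at padded keys). Returns the context tensor and
    the detached attention weights.
    """
    logits = np.matmul(q.data, np.swapaxes(k.data, -1, -2)) * scale + addmask
    logits -= logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=-1, keepdims=True)
    ctx = np.matmul(w, v.data)

    def bw(g, q=q, k=k, v=v, w=w, scale=scale):
        sink = out._grad_sink
        gv = np.matmul(np.swapaxes(w, -1, -2), g)
        gw = np.matmul(g, np.swapaxes(v.data, -1, -2))
        gl = w * (gw - (gw * w).sum(axis=-1, keepdims=True))
        Tensor._accum(sink, q, np.matmul(gl, k.data) * scale)
        Tensor._accum(sink, k, np.matmul(np.swapaxes(gl, -1, -2), q.data) * scale)
        Tensor._accum(sink, v, gv)

    out = q._make(ctx, (q, k, v), bw)
    return out, w


class AdamW:
    """Decoupled weight-decay Adam over a flat parameter list."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
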