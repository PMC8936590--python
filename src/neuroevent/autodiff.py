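"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Internal infrastructure for the joint model: just the primitives the
encoder, CRF and relation layer need.  Gradients propagate through a
topologically sorted tape; broadcasting is undone by summing over the
broadcast axes.  Gradient buffers are allocated lazily on first
accumulation.
"""

from __future__ import annotations

import numpy as np


def _accum(t: "Tensor", g) -> None:
    if t.grad is None:
        t.grad = np.array(g, dtype=float)
    else:
        t.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _is_basic_index(idx) -> bool:
    parts = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(p, (int, np.integer, slice)) or p is None for p in parts)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                _accum(self, _unbroadcast(g, self.data.shape))
            if other.requires_grad:
                _accum(other, _unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                _accum(self, _unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                _accum(
                    self,
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape),
                )
            if other.requires_grad:
                _accum(
                    other,
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape),
                )

        return self._make(self.data @ other.data, (self, other), backward)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # ---- shape ops ------------------------------------------------------

    def __getitem__(self, idx):
        basic = _is_basic_index(idx)

        def backward(g):
            if not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if basic:  # basic slices never alias, so += is safe and fast
                self.grad[idx] += g
            else:
                np.add.at(self.grad, idx, g)

        return self._make(self.data[idx], (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                _accum(self, g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                _accum(self, np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            _accum(self, np.broadcast_to(gg, self.data.shape))

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    # ---- nonlinearities -------------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                _accum(self, g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward(g):
            if self.requires_grad:
                _accum(self, g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = np.exp(self.data - m)
        total = shifted.sum(axis=axis, keepdims=True)
        out_data = np.log(total) + m
        soft = shifted / total

        def backward(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                _accum(self, gg * soft)

        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        return self._make(out_data, (self,), backward)


try:  # C-speed sigmoid when SciPy is present (it is in the test image)
    from scipy.special import expit as _sigmoid  # type: ignore
except ImportError:  # pragma: no cover

    def _sigmoid(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(np.asarray(x, dtype=float))
        x = np.asarray(x, dtype=float)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        e = np.exp(x[~pos])
        out[~pos] = e / (1.0 + e)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    _accum(t, g[tuple(sl)])

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):

        def backward(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    _accum(t, np.take(g, i, axis=axis))

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Summed binary cross-entropy over masked logit positions (stable)."""
    x, y = logits.data, targets
    loss = mask * (np.maximum(x, 0.0) - x * y + np.log1p(np.exp(-np.abs(x))))
    out = Tensor(loss.sum())

    def backward(g):
        if logits.requires_grad:
            _accum(logits, g * mask * (_sigmoid(x) - y))

    if logits.requires_grad:
        out.requires_grad = True
        out._parents = (logits,)
        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-10):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def reset_state(self):
        """Forget moment estimates (used for warm restarts)."""
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0
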