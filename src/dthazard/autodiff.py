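"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module exists because the modelling layer needs gradients of a scalar
loss with respect to both network parameters (training) and network inputs
(integrated gradients), and no deep-learning framework is assumed to be
available at run time.  It implements the small set of tensor operations the
hazard models require: broadcasting arithmetic, batched matrix products,
elementwise nonlinearities, softmax, reductions, reshapes and concatenation.

The design is a conventional dynamic tape: every operation returns a new
:class:`Tensor` holding references to its parents and a closure that
accumulates gradients into them.  ``Tensor.backward()`` topologically sorts
the tape and runs the closures in reverse.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "linear", "layer_norm", "Adam", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            # weak promotion: plain scalars adopt this tensor's dtype
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other))

    def _make(self, data: np.ndarray, parents: Iterable["Tensor"]) -> "Tensor":
        if not _GRAD_ENABLED:
            return Tensor(data)
        parents = tuple(parents)
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        out._parents = parents
        return out

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        """Accumulate a gradient contribution.

        ``own=True`` promises ``grad`` is a freshly allocated buffer with this
        tensor's exact shape/dtype that no other node aliases, so it can be
        adopted without a copy.
        """
        if not self.requires_grad:
            return
        if self.grad is None:
            if own and grad.shape == self.data.shape and grad.dtype == self.data.dtype:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- basic properties -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        if out._parents:
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = self._make(-self.data, (self,))
        if out._parents:
            out._backward = lambda: self._accum(-out.grad, own=True)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape), own=True)

        if out._parents:
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data / other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape), own=True)
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape),
                    own=True,
                )

        if out._parents:
            out._backward = backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out = self._make(self.data**exponent, (self,))

        def backward():
            self._accum(out.grad * exponent * self.data ** (exponent - 1), own=True)

        if out._parents:
            out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other))

        def backward():
            a, b, g = self.data, other.data, out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape), own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape), own=True)

        if out._parents:
            out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self) -> "Tensor":
        out = self._make(np.exp(self.data), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * out.data, own=True)
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad / self.data, own=True)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(s, (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * s * (1.0 - s), own=True)
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = self._make(t, (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * (1.0 - t**2), own=True)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = self._make(np.where(mask, self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * mask, own=True)
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation, adequate for an encoder activation
        x = self.data
        c = x.dtype.type(np.sqrt(2.0 / np.pi))
        k = x.dtype.type(0.044715)
        x2 = x * x
        t = np.tanh(c * (x + k * (x2 * x)))
        out = self._make(x.dtype.type(0.5) * x * (1.0 + t), (self,))

        def backward():
            dinner = c * (1.0 + 3.0 * k * x2)
            dgelu = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._accum(out.grad * dgelu.astype(x.dtype), own=True)

        if out._parents:
            out._backward = backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient passes through only where not clipped."""
        mask = (self.data > lo) & (self.data < hi)
        out = self._make(np.clip(self.data, lo, hi), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad * mask, own=True)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        s = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(s, out=s)
        s /= s.sum(axis=axis, keepdims=True)
        out = self._make(s, (self,))

        def backward():
            g = out.grad
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)), own=True)

        if out._parents:
            out._backward = backward
        return out

    # -- reductions and shape ops --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(a % self.ndim for a in axes)
                shape = [1 if i in axes else s for i, s in enumerate(self.shape)]
                g = g.reshape(shape)
            self._accum(np.broadcast_to(g, self.shape))

        if out._parents:
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in ((axis,) if isinstance(axis, int) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,))
        if out._parents:
            out._backward = lambda: self._accum(out.grad.transpose(inv))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = self._make(self.data[idx], (self,))

        def backward():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        if out._parents:
            out._backward = backward
        return out

    # -- graph traversal ------------------------------------------------------

    def broadcast_to(self, shape: tuple[int, ...]) -> "Tensor":
        out = self._make(np.broadcast_to(self.data, shape), (self,))
        if out._parents:
            out._backward = lambda: self._accum(_unbroadcast(out.grad, self.shape))
        return out

    def backward(self, grad: np.ndarray | None = None, free_graph: bool = True) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given).

        With ``free_graph`` (default) the tape is dismantled afterwards,
        breaking the tensor/closure reference cycles so large intermediate
        activations are reclaimed immediately.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires an explicit grad")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: tapes can exceed the recursion limit
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                if node.requires_grad or node._parents:
                    node._backward()
        if free_graph:
            for node in topo:
                is_leaf = node.requires_grad and not node._parents
                node._backward = None
                node._parents = ()
                if node is not self and not is_leaf:
                    node.grad = None


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused affine map ``x @ w + b`` (one tape node instead of two).

    ``x`` may carry arbitrary leading batch dimensions; ``w`` is ``(d, k)``
    and ``b`` is ``(k,)``.
    """
    if not _GRAD_ENABLED:
        return Tensor(x.data @ w.data + b.data)
    out = Tensor(x.data @ w.data + b.data,
                 requires_grad=x.requires_grad or w.requires_grad or b.requires_grad)
    out._parents = (x, w, b)

    def backward():
        g = out.grad
        g2 = g.reshape(-1, g.shape[-1])
        if x.requires_grad:
            x._accum(g @ w.data.T, own=True)
        if w.requires_grad:
            w._accum(x.data.reshape(-1, x.data.shape[-1]).T @ g2, own=True)
        if b.requires_grad:
            b._accum(g2.sum(axis=0), own=True)

    out._backward = backward
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learnable gain and bias."""
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=xd.dtype))
    y = xc * inv
    if not _GRAD_ENABLED:
        return Tensor(y * gain.data + bias.data)
    out = Tensor(y * gain.data + bias.data,
                 requires_grad=x.requires_grad or gain.requires_grad or bias.requires_grad)
    out._parents = (x, gain, bias)

    def backward():
        g = out.grad
        gg = g * gain.data
        lead = tuple(range(g.ndim - 1))
        gain._accum((g * y).sum(axis=lead), own=True)
        bias._accum(g.sum(axis=lead), own=True)
        # dx = inv * (gg - mean(gg) - y * mean(gg * y)) over the last axis
        m1 = gg.mean(axis=-1, keepdims=True)
        m2 = (gg * y).mean(axis=-1, keepdims=True)
        x._accum(inv * (gg - m1 - y * m2), own=True)

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    if not _GRAD_ENABLED:
        return Tensor(data)
    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    out._parents = tuple(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * data.ndim
            idx[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(idx)])

    out._backward = backward
    return out


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
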