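"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine implements exactly the primitives needed by the transformer
models in this package: broadcast-aware arithmetic, batched matmul,
shape manipulation, softmax / layer-norm / GELU fused primitives,
inverted dropout and a cross-entropy loss. Gradients are accumulated by
a topological backward sweep from a scalar loss.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Tensor", "Parameter", "cat", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(grad):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            return (-grad,)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only supported by scalars")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(grad):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.expand_dims(grad, -1) * b
                gb = (np.expand_dims(grad, -1) * a).reshape(-1, b.shape[0]).sum(0)
            elif a.ndim == 1:
                ga = grad @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, grad)
            else:
                ga = grad @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ grad
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(grad):
            return (grad.reshape(old),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(grad):
            return (grad.transpose(inv),)

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        shape = self.shape

        def backward(grad):
            full = np.zeros(shape, dtype=grad.dtype)
            np.add.at(full, idx, grad)
            return (full,)

        return self._make(self.data[idx], (self,), backward)

    def broadcast_to(self, shape):
        def backward(grad):
            return (_unbroadcast(grad, self.shape),)

        return self._make(np.broadcast_to(self.data, shape), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- fused primitives --------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(grad):
            dot = (grad * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (grad - dot),)

        return self._make(out_data, (self,), backward)

    def gelu(self):
        x = self.data
        c = math.sqrt(2.0 / math.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(grad):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            return (grad * d,)

        return self._make(out_data, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis then apply an affine map."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * gamma.data + beta.data

        def backward(grad):
            n = x.shape[-1]
            g = grad * gamma.data
            dxhat_sum = g.sum(axis=-1, keepdims=True)
            dxhat_dot = (g * xhat).sum(axis=-1, keepdims=True)
            dx = inv * (g - dxhat_sum / n - xhat * dxhat_dot / n)
            dgamma = _unbroadcast(grad * xhat, gamma.shape)
            dbeta = _unbroadcast(grad, beta.shape)
            return (dx, dgamma, dbeta)

        return self._make(out_data, (self, gamma, beta), backward)

    def dropout(self, p: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when ``rng`` is None (eval mode)."""
        if rng is None or p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)

        def backward(grad):
            return (grad * mask,)

        return self._make(self.data * mask, (self,), backward)

    # -- autograd ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad += g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = np.asarray(pg)
        # leaves reached exactly once keep grads set inside the loop; flush rest
        for node in topo:
            g = grads.pop(id(node), None)
            if g is not None:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad += g


class Parameter(Tensor):
    """A trainable leaf tensor (float64 for numerically stable training)."""

    __slots__ = ("trainable",)

    def __init__(self, data, trainable: bool = True):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=trainable)
        self.trainable = trainable


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(grad):
            return tuple(np.split(grad, splits, axis=axis))

        out._backward = backward
    return out


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row ``logits``."""
    x = logits.data
    n = x.shape[0]
    shifted = x - x.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - logsumexp
    loss_val = -logp[np.arange(n), labels].mean()

    def backward(grad):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return (grad * p / n,)

    out = Tensor(loss_val)
    if logits.requires_grad:
        out.requires_grad = True
        out._parents = (logits,)
        out._backward = backward
    return out
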