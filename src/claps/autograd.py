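"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the transformer encoder, projection head,
predictor and contrastive loss need: broadcast-aware elementwise arithmetic,
(batched) matrix products, reductions, `exp`/`log`/`relu`/`sigmoid`/`pow`,
shape manipulation, an embedding-row gather, and an Adam optimizer.
All arithmetic is float64, so forward passes are bit-reproducible on CPU.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "softmax", "layer_norm", "embedding_rows", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._prev: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, prev: tuple["Tensor", ...]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = prev
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            # take ownership of g; ensure it is writable for later additions
            self.grad = g if g.flags.writeable else g.copy()
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = self._make(self.data + other.data, (self, other))

        def backward():
            ga = _unbroadcast(out.grad, self.data.shape)
            gb = _unbroadcast(out.grad, other.data.shape)
            if ga is gb and self.requires_grad and other.requires_grad:
                gb = gb.copy()  # never hand one buffer to two owners
            self._accumulate(ga)
            other._accumulate(gb)

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = self._make(self.data * other.data, (self, other))

        def backward():
            self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float) -> "Tensor":
        out = self._make(self.data**p, (self,))

        def backward():
            self._accumulate(out.grad * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = self._make(np.matmul(self.data, other.data), (self, other))

        def backward():
            ga = np.matmul(out.grad, other.data.swapaxes(-1, -2))
            gb = np.matmul(self.data.swapaxes(-1, -2), out.grad)
            self._accumulate(_unbroadcast(ga, self.data.shape))
            other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    # -- nonlinearities -------------------------------------------------------

    def relu(self) -> "Tensor":
        out = self._make(np.maximum(self.data, 0.0), (self,))

        def backward():
            self._accumulate(out.grad * (self.data > 0.0))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        out = self._make(np.exp(self.data), (self,))

        def backward():
            self._accumulate(out.grad * out.data)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,))

        def backward():
            self._accumulate(out.grad / self.data)

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        # stable two-branch evaluation
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = self._make(s, (self,))

        def backward():
            self._accumulate(out.grad * out.data * (1.0 - out.data))

        out._backward = backward
        return out

    # -- reductions and shape -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = self._make(self.data.reshape(*shape), (self,))

        def backward():
            self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        out = self._make(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)

        def backward():
            self._accumulate(out.grad.transpose(*inv))

        out._backward = backward
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = self._make(self.data.swapaxes(a, b), (self,))

        def backward():
            self._accumulate(out.grad.swapaxes(a, b))

        out._backward = backward
        return out

    # -- autodiff driver ------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from a scalar output through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            # break the node <-> closure reference cycle and drop interior
            # grads so the graph is freed promptly by refcounting
            interior = bool(node._prev)
            node._backward = None
            node._prev = ()
            if interior and node is not self:
                node.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (max-shifted), as a single
    primitive with the closed-form Jacobian-vector product."""
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    y = e / e.sum(axis=axis, keepdims=True)
    out = x._make(y, (x,))

    def backward():
        g = out.grad
        x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = backward
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis with learnable gain and bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centred = x - mu
    var = (centred * centred).mean(axis=-1, keepdims=True)
    return centred * (var + eps) ** -0.5 * gain + bias


def embedding_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Gather rows of `table` at integer `ids`; gradients scatter-add back."""
    ids = np.asarray(ids)
    out = Tensor(table.data[ids])
    out.requires_grad = table.requires_grad
    if out.requires_grad:
        out._prev = (table,)

        def backward():
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, ids, out.grad)

        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params: list[Tensor] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled


def gradient_check(f: Callable[[Sequence[Tensor]], Tensor], params: Sequence[Tensor],
                   eps: float = 1e-6) -> float:
    """Max abs difference between analytic and central-difference gradients.

    Test utility; exhaustive over every parameter entry, so keep inputs tiny.
    """
    loss = f(params)
    loss.backward()
    analytic = [p.grad.copy() if p.grad is not None else np.zeros_like(p.data)
                for p in params]
    worst = 0.0
    for p, g in zip(params, analytic):
        flat = p.data.ravel()
        for k in range(flat.size):
            orig = flat[k]
            flat[k] = orig + eps
            hi = float(f(params).data)
            flat[k] = orig - eps
            lo = float(f(params).data)
            flat[k] = orig
            num = (hi - lo) / (2 * eps)
            worst = max(worst, abs(num - g.ravel()[k]))
    return worst
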