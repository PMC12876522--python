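"""Minimal reverse-mode automatic differentiation over numpy arrays.

Covers exactly the operations the episodic and batch training losses need:
affine maps, ReLU, broadcasting add/sub/mul, pairwise Euclidean distances,
column means, and a fused binary-cross-entropy-with-logits loss.  Gradients
are checked against central differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires_grad) -> Tensor:
    out = Tensor(data)
    out.requires_grad = requires_grad
    if requires_grad:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


def _accumulate(node: Tensor, grad: np.ndarray) -> None:
    if not node.requires_grad:
        return
    if node.grad is None:
        node.grad = np.zeros_like(node.data)
    node.grad += _unbroadcast(grad, node.data.shape)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward():
        _accumulate(a, out.grad)
        _accumulate(b, out.grad)

    out = _make(out_data, (a, b), backward, a.requires_grad or b.requires_grad)
    return out


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward():
        _accumulate(a, out.grad)
        _accumulate(b, -out.grad)

    out = _make(out_data, (a, b), backward, a.requires_grad or b.requires_grad)
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward():
        _accumulate(a, out.grad * b.data)
        _accumulate(b, out.grad * a.data)

    out = _make(out_data, (a, b), backward, a.requires_grad or b.requires_grad)
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward():
        _accumulate(a, out.grad @ b.data.T)
        _accumulate(b, a.data.T @ out.grad)

    out = _make(out_data, (a, b), backward, a.requires_grad or b.requires_grad)
    return out


def relu(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward():
        _accumulate(a, out.grad * (a.data > 0.0))

    out = _make(out_data, (a,), backward, a.requires_grad)
    return out


def mean_axis0(a) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.mean(axis=0)
    n = a.data.shape[0]

    def backward():
        _accumulate(a, np.broadcast_to(out.grad / n, a.data.shape))

    out = _make(out_data, (a,), backward, a.requires_grad)
    return out


def cdist(a, b, eps: float = 1e-12) -> Tensor:
    """Pairwise Euclidean distances: (n, d) x (m, d) -> (n, m).

    The gradient at a coincident pair is taken as 0 (subgradient choice).
    """
    a, b = _as_tensor(a), _as_tensor(b)
    diff = a.data[:, None, :] - b.data[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    def backward():
        safe = np.maximum(dist, eps)
        scale = (out.grad / safe)[:, :, None] * diff
        _accumulate(a, scale.sum(axis=1))
        _accumulate(b, -scale.sum(axis=0))

    out = _make(dist, (a, b), backward, a.requires_grad or b.requires_grad)
    return out


def bce_with_logits(logits, targets) -> Tensor:
    """Mean binary cross-entropy between sigmoid(logits) and 0/1 targets."""
    logits = _as_tensor(logits)
    y = np.asarray(targets, dtype=float)
    z = logits.data
    # log(1 + e^z) computed stably
    loss = np.logaddexp(0.0, z) - y * z
    out_data = loss.mean()

    def backward():
        sig = 1.0 / (1.0 + np.exp(-z))
        _accumulate(logits, out.grad * (sig - y) / y.size)

    out = _make(out_data, (logits,), backward, logits.requires_grad)
    return out


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable elementwise sigmoid (plain numpy, no graph)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AdamW:
    """AdamW optimiser (decoupled weight decay) over a list of Tensors."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g**2
            m_hat = self._m[i] / (1 - b1**self.t)
            v_hat = self._v[i] / (1 - b2**self.t)
            p.data -= self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params: list[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
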