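"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the coordinate networks and the
physics-informed loss need: dense affine layers, elementwise arithmetic,
``sin``/``softplus``/``sigmoid``/``tanh``/``relu``/``abs``, reductions, 2-D
valid correlation against fixed kernels, reshaping and slicing.  Gradients
flow to :class:`Tensor` leaves with ``requires_grad=True``; kernel weights in
correlations are treated as constants.

This is deliberately a small engine, not a framework: full-batch training on
modest grids is the only workload, and a fresh topological sort per backward
pass keeps the implementation obvious.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import convolve2d, correlate2d

ArrayLike = Union[np.ndarray, float, int]

__all__ = ["Tensor", "constant", "correlate2d_valid", "concat", "Adam", "grad_check"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple["Tensor", ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(x: Union["Tensor", ArrayLike]) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _node(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._push(_unbroadcast(g, self.shape))
            other._push(_unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._push(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._push(_unbroadcast(g * other.data, self.shape))
            other._push(_unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._push(_unbroadcast(g / other.data, self.shape))
            other._push(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._push(g * p * self.data ** (p - 1))

        return self._node(self.data**p, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._push(g @ other.data.T)
            other._push(self.data.T @ g)

        return self._node(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- elementwise nonlinearities ------------------------------------
    def sin(self) -> "Tensor":
        def backward(g):
            self._push(g * np.cos(self.data))

        return self._node(np.sin(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._push(g * (1.0 - out_data**2))

        return self._node(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        def backward(g):
            self._push(g * (self.data > 0))

        return self._node(np.maximum(self.data, 0.0), (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._push(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), backward)

    def softplus(self) -> "Tensor":
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._push(g * sig)

        return self._node(out_data, (self,), backward)

    def swish(self) -> "Tensor":
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._push(g * (sig + self.data * sig * (1.0 - sig)))

        return self._node(self.data * sig, (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def backward(g):
            self._push(g * sign)

        return self._node(np.abs(self.data), (self,), backward)

    # -- reductions / shape --------------------------------------------
    def sum(self) -> "Tensor":
        def backward(g):
            self._push(np.broadcast_to(g, self.shape).copy())

        return self._node(self.data.sum(), (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            self._push(np.broadcast_to(g / n, self.shape).copy())

        return self._node(self.data.mean(), (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def backward(g):
            self._push(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._push(full)

        return self._node(self.data[idx], (self,), backward)

    # -- backward pass --------------------------------------------------
    def _push(self, g: np.ndarray) -> None:
        if self.requires_grad:
            self._accum(g)
        elif self._backward is not None:
            self._pending_accum(g)

    def _pending_accum(self, g: np.ndarray) -> None:
        # interior node: stash gradient until its own backward fires
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar output to all requires_grad leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: List[Tensor] = []
        seen = set()
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
                if id(p) not in seen and (p._backward is not None or p.requires_grad):
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if not node.requires_grad:
                    node.grad = None  # free interior gradients


def constant(x: ArrayLike) -> Tensor:
    return Tensor(x, requires_grad=False)


def correlate2d_valid(x: Tensor, kernel: np.ndarray) -> Tensor:
    """Valid-mode correlation of a 2-D tensor with a fixed kernel."""
    kernel = np.asarray(kernel, dtype=np.float64)

    def backward(g):
        x._push(convolve2d(g, kernel, mode="full"))

    return x._node(correlate2d(x.data, kernel, mode="valid"), (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._push(g[tuple(sl)])

    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    node = tensors[0]._node(out_data, tuple(tensors), backward)
    return node


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def grad_check(
    loss_fn: Callable[[], Tensor],
    params: Sequence[Tensor],
    eps: float = 1e-6,
    n_samples: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Max relative error between backprop and central finite differences.

    Samples ``n_samples`` coordinates per parameter tensor.
    """
    rng = rng or np.random.default_rng(0)
    for p in params:
        p.grad = None
    loss = loss_fn()
    loss.backward()
    analytic = [None if p.grad is None else p.grad.copy() for p in params]
    worst = 0.0
    for p, g in zip(params, analytic):
        if g is None:
            continue
        flat_idx = rng.choice(p.data.size, size=min(n_samples, p.data.size), replace=False)
        for k in flat_idx:
            idx = np.unravel_index(k, p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            lp = float(loss_fn().data)
            p.data[idx] = orig - eps
            lm = float(loss_fn().data)
            p.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(g[idx]), 1e-8)
            worst = max(worst, abs(fd - g[idx]) / denom)
    return worst
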