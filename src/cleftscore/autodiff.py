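"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical engine behind the differentiable toy generator, the
perceptual distance, the noise-randomness regularizer, and both optimization
loops (latent inversion and model adaptation). It implements exactly the op
set those components need — elementwise arithmetic with broadcasting, matrix
multiply, 3×3 same-padding convolution, 2× average pooling / nearest
upsampling, slicing, reductions, and a few pointwise nonlinearities — as a
tape of :class:`Tensor` nodes with a topological-order backward pass.

Gradients are validated against central finite differences in the test
suite (relative error < 1e-3 on the toy generator).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data),
                                   other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow_const(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow_const(-1.0)

    def pow_const(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def square(self) -> "Tensor":
        return self * self

    def sqrt(self) -> "Tensor":
        return self.pow_const(0.5)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- linear algebra ----------------------------------------------------

    def matvec(self, x: "Tensor") -> "Tensor":
        """(m, n) @ (n,) -> (m,)."""
        x = self._lift(x)
        out = Tensor(self.data @ x.data, parents=(self, x))
        out._backward = lambda g: (self._accum(np.outer(g, x.data)),
                                   x._accum(self.data.T @ g))
        return out

    # -- pointwise nonlinearities -------------------------------------------

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        pos = self.data > 0
        out = Tensor(np.where(pos, self.data, slope * self.data),
                     parents=(self,))
        out._backward = lambda g: self._accum(np.where(pos, g, slope * g))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    # -- image ops (C, H, W layout) -----------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """3×3 same-padding convolution: (C,H,W) × (O,C,3,3) -> (O,H,W)."""
        weight = self._lift(weight)
        x = self.data
        w = weight.data
        C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        y = np.einsum("ocij,chwij->ohw", w, win, optimize=True)
        parents = (self, weight)
        if bias is not None:
            bias = self._lift(bias)
            y = y + bias.data[:, None, None]
            parents = (self, weight, bias)
        out = Tensor(y, parents=parents)

        def bwd(g):
            weight._accum(np.einsum("ohw,chwij->ocij", g, win, optimize=True))
            gp = np.pad(g, ((0, 0), (1, 1), (1, 1)))
            gwin = np.lib.stride_tricks.sliding_window_view(
                gp, (3, 3), axis=(1, 2))
            wf = w[:, :, ::-1, ::-1]
            self._accum(np.einsum("ocij,ohwij->chw", wf, gwin, optimize=True))
            if bias is not None:
                bias._accum(g.sum(axis=(1, 2)))

        out._backward = bwd
        return out

    def avg_pool2(self) -> "Tensor":
        """2×2 mean pooling on the trailing two axes (sides must be even)."""
        *lead, H, W = self.data.shape
        shaped = self.data.reshape(*lead, H // 2, 2, W // 2, 2)
        out = Tensor(shaped.mean(axis=(-3, -1)), parents=(self,))

        def bwd(g):
            gg = np.repeat(np.repeat(g, 2, axis=-1), 2, axis=-2) / 4.0
            self._accum(gg)

        out._backward = bwd
        return out

    def upsample2(self) -> "Tensor":
        """Nearest-neighbour 2× upsampling on the trailing two axes."""
        out = Tensor(np.repeat(np.repeat(self.data, 2, axis=-1), 2, axis=-2),
                     parents=(self,))

        def bwd(g):
            *lead, H2, W2 = g.shape
            gg = g.reshape(*lead, H2 // 2, 2, W2 // 2, 2).sum(axis=(-3, -1))
            self._accum(gg)

        out._backward = bwd
        return out


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 0.05,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = self._m[k] / (1 - self.b1 ** self.t)
            vhat = self._v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
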