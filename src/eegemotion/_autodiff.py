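"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just the operations the attention-residual network needs: broadcast
arithmetic, matmul, 1-D same-padded convolution, concatenation, means,
relu/sigmoid, and a fused softmax cross-entropy.  Gradients are accumulated
on a topologically sorted tape; correctness is pinned by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum out broadcast dimensions so grad matches the original shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ---------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)
        out._backward = backward
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data - other.data, (self, other))

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)
        out._backward = backward
        return out

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = backward
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), (self,))
        out._backward = lambda g: (g * 0.5 / np.sqrt(self.data),)
        return out

    def mean(self, axis=None, keepdims=False):
        out = Tensor(self.data.mean(axis=axis, keepdims=keepdims), (self,))
        count = self.data.size if axis is None else self.data.shape[axis]

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape) / count,)
        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            return g @ other.data.T, self.data.T @ g
        out._backward = backward
        return out

    # -- nonlinearities -----------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, (self,))
        out._backward = lambda g: (g * s * (1 - s),)
        return out

    # -- backprop driver ----------------------------------------------------

    def backward(self):
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            order.append(node)
        visit(self)

        for node in order:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad:
                    parent.grad = parent.grad + g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 1-D convolution (cross-correlation) for odd kernel width.

    x: (B, C_in, L); weight: (C_out, C_in, K); bias: (C_out,) → (B, C_out, L).
    """
    B, C_in, L = x.data.shape
    C_out, _, K = weight.data.shape
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,Cin,L,K)
    # im2col + BLAS matmul: rows index (batch, position), columns (channel, tap)
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * L, C_in * K)
    w2 = weight.data.reshape(C_out, C_in * K)
    out_data = (cols2 @ w2.T).reshape(B, L, C_out).transpose(0, 2, 1) \
        + bias.data[None, :, None]
    out = Tensor(out_data, (x, weight, bias))

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * L, C_out)
        grad_w = (g2.T @ cols2).reshape(C_out, C_in, K)
        grad_b = g.sum(axis=(0, 2))
        # grad wrt input: correlate padded upstream grad with the flipped kernel
        gp = np.pad(g, ((0, 0), (0, 0), (pad, pad)))
        gcols = np.lib.stride_tricks.sliding_window_view(gp, K, axis=2)  # (B,Cout,L,K)
        gcols2 = np.ascontiguousarray(gcols.transpose(0, 2, 1, 3)).reshape(B * L, C_out * K)
        wf2 = np.ascontiguousarray(
            weight.data[:, :, ::-1].transpose(0, 2, 1)).reshape(C_out * K, C_in)
        grad_x = (gcols2 @ wf2).reshape(B, L, C_in).transpose(0, 2, 1)
        return grad_x, grad_w, grad_b
    out._backward = backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, L) → (B, C) mean over positions."""
    return x.mean(axis=2)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; fused for numerical stability."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = len(targets)
    loss = -np.log(np.maximum(probs[np.arange(n), targets], 1e-300)).mean()
    out = Tensor(loss, (logits,))

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), targets] -= 1.0
        return (g * grad / n,)
    out._backward = backward
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Standard Adam over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:          # parameter unused by the current graph
                continue
            m *= b1; m += (1 - b1) * g
            v *= b2; v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
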