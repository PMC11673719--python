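"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for an encoder-decoder transformer: broadcasting
arithmetic, batched matmul, reshape/transpose, ReLU, softmax, a fused
layer-norm, embedding gather and a fused masked softmax cross-entropy.
Everything runs in float32; gradients are accumulated on a tape and released
after each backward pass.  Correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        """Add *g* to the stored gradient.

        ``own=True`` promises that *g* is a freshly allocated array the
        caller will not reuse, letting it be stored without a copy.
        """
        if self.grad is None:
            if own and g.dtype == DTYPE:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=DTYPE)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.backward_fn is not None:
                node.backward_fn(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        if not isinstance(other, Tensor):
            data = self.data + np.asarray(other, dtype=DTYPE)
            out = Tensor(data, parents=(self,))
            out.backward_fn = lambda g: self.requires_grad and self._accumulate(
                _unbroadcast(g, self.shape)
            )
            return out
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out.backward_fn = bw
        return out

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        if not isinstance(other, Tensor):
            factor = np.asarray(other, dtype=DTYPE)
            out = Tensor(self.data * factor, parents=(self,))
            out.backward_fn = lambda g: self.requires_grad and self._accumulate(
                _unbroadcast(g * factor, self.shape)
            )
            return out
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape),
                                 own=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape),
                                  own=True)

        out.backward_fn = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape), own=True)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape), own=True)

        out.backward_fn = bw
        return out

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out.backward_fn = lambda g: self.requires_grad and self._accumulate(
            g.reshape(orig)
        )
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out.backward_fn = lambda g: self.requires_grad and self._accumulate(
            g.transpose(inv)
        )
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out.backward_fn = lambda g: self.requires_grad and self._accumulate(
            g * mask, own=True)
        return out


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data: np.ndarray) -> Tensor:
    return Tensor(data)


def softmax(x: Tensor) -> Tensor:
    """Softmax along the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=-1, keepdims=True)
            x._accumulate((g - dot) * y, own=True)

    out.backward_fn = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the last axis with learnable scale/shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    d = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape), own=True)
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape), own=True)
        if x.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (
                (gx * xhat).mean(axis=-1, keepdims=True)
            )
            x._accumulate(term * inv, own=True)

    out.backward_fn = bw
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``table[ids]`` with scatter-add backward."""
    out = Tensor(table.data[ids], parents=(table,))

    def bw(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
            table._accumulate(acc, own=True)

    out.backward_fn = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rate==0 or rng is None (inference)."""
    if rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape, dtype=DTYPE) >= rate).astype(DTYPE)
    mask /= DTYPE(1.0 - rate)
    return x * Tensor(mask)


def masked_softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, mask: np.ndarray
) -> tuple[Tensor, float]:
    """Mean cross-entropy over positions where *mask* is true.

    Returns ``(loss_tensor, accuracy)``; the accuracy (fraction of masked
    positions where the argmax equals the label) is a by-product of the same
    forward pass.  Defined as loss 0 / accuracy 0 for an all-masked batch.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = int(mask.sum())
    if n == 0:
        return Tensor(np.zeros(()), parents=(logits,), backward_fn=lambda g: None), 0.0
    picked = np.take_along_axis(p, labels[..., None], axis=-1)[..., 0]
    logp = np.log(np.maximum(picked, 1e-30))
    loss_val = -(logp * mask).sum() / n
    correct = (p.argmax(axis=-1) == labels) & mask.astype(bool)
    acc = float(correct.sum() / n)
    out = Tensor(np.asarray(loss_val), parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            grad = p.copy()
            np.put_along_axis(
                grad, labels[..., None],
                np.take_along_axis(grad, labels[..., None], axis=-1) - 1.0,
                axis=-1)
            grad *= (mask / n)[..., None]
            logits._accumulate(grad * g, own=True)

    out.backward_fn = bw
    return out, acc
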