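"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations needed for 1D convolutional
encoder/decoder generators and patch discriminators: strided 1D
convolution with TensorFlow-style "same" padding, instance
normalization, pointwise nonlinearities, nearest-neighbour upsampling,
channel concatenation with non-differentiable condition channels, and
the scalar loss reductions (binary cross-entropy on logits, mean
absolute error).

Tensors carry data of shape ``(batch, channels, length)`` (or scalar
shape for losses).  Gradient correctness is property-tested against
finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "no_grad",
    "conv1d",
    "relu",
    "leaky_relu",
    "sigmoid",
    "instance_norm",
    "channel_norm",
    "upsample_nearest",
    "concat_condition",
    "add",
    "weighted_sum",
    "bce_with_logits",
    "mse_to_constant",
    "l1_mean",
    "same_padding",
    "Adam",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A node in the computation graph.

    ``data`` is an ``np.ndarray`` (float64).  ``grad`` is filled by
    :meth:`backward`.  Operations record a closure that accumulates
    gradients into their parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.shape != ():
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(1.0)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Scalar arithmetic, used to combine loss terms.
    def __add__(self, other):
        return _scalar_binary(self, other, "add")

    __radd__ = __add__

    def __mul__(self, other):
        return _scalar_binary(self, other, "mul")

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (always requires gradient)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _scalar_binary(a: Tensor, other, op: str) -> Tensor:
    if isinstance(other, Tensor):
        b = other
    else:
        b = Tensor(float(other))
    if op == "add":
        data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(g)
            if b.requires_grad:
                b._accumulate(g)

    else:
        data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * b.data)
            if b.requires_grad:
                b._accumulate(g * a.data)

    return _make(data, (a, b), backward)


def same_padding(length: int, kernel: int, stride: int) -> tuple[int, int]:
    """TensorFlow-style 'same' padding (extra sample on the right)."""
    out_len = -(-length // stride)  # ceil
    total = max((out_len - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """1D convolution (cross-correlation) with 'same' padding.

    ``x``: (N, C_in, L); ``w``: (C_out, C_in, K); ``b``: (C_out,).
    Output length is ``ceil(L / stride)``.
    """
    n, c_in, length = x.data.shape
    c_out, c_in_w, k = w.data.shape
    if c_in != c_in_w:
        raise ValueError(f"channel mismatch: input {c_in}, kernel {c_in_w}")
    pl, pr = same_padding(length, k, stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    l_out = -(-length // stride)
    slices = [xp[:, :, t : t + stride * l_out : stride] for t in range(k)]
    y = np.broadcast_to(b.data[None, :, None], (n, c_out, l_out)).copy()
    for t in range(k):
        # (C_out, C_in) @ (N, C_in, L_out) -> (N, C_out, L_out)
        y += np.matmul(w.data[:, :, t], slices[t])

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for t in range(k):
                dw[:, :, t] = np.matmul(g, slices[t].transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for t in range(k):
                dxp[:, :, t : t + stride * l_out : stride] += np.matmul(
                    w.data[:, :, t].T, g
                )
            x._accumulate(dxp[:, :, pl : pl + length])

    return _make(y, (x, w, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return _make(x.data * mask, (x,), lambda g: x._accumulate(g * mask))


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    factor = np.where(x.data > 0, 1.0, alpha)
    return _make(x.data * factor, (x,), lambda g: x._accumulate(g * factor))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    return _make(s, (x,), lambda g: x._accumulate(g * s * (1.0 - s)))


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each (sample, channel) series over the time axis.

    No learnable affine parameters (matching the affine-free instance
    normalization of the reference CycleGAN generator).
    """
    mu = x.data.mean(axis=2, keepdims=True)
    var = x.data.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g):
        gm = g.mean(axis=2, keepdims=True)
        gx = (g * xhat).mean(axis=2, keepdims=True)
        x._accumulate(inv * (g - gm - xhat * gx))

    return _make(xhat, (x,), backward)


def channel_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize across channels independently at every time step.

    Unlike instance normalization (which couples all time steps through
    the temporal mean/variance), this keeps every output sample a
    function of the same time positions as its input, so convolutional
    receptive fields remain exact.
    """
    mu = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g):
        gm = g.mean(axis=1, keepdims=True)
        gx = (g * xhat).mean(axis=1, keepdims=True)
        x._accumulate(inv * (g - gm - xhat * gx))

    return _make(xhat, (x,), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    y = np.repeat(x.data, factor, axis=2)

    def backward(g):
        n, c, l2 = g.shape
        x._accumulate(g.reshape(n, c, l2 // factor, factor).sum(axis=3))

    return _make(y, (x,), backward)


def concat_condition(x: Tensor, cond: np.ndarray) -> Tensor:
    """Concatenate constant condition channels to the signal.

    ``cond`` carries no gradient; the backward pass routes gradients to
    the signal channels only.
    """
    n, c, length = x.data.shape
    if cond.shape[0] != n or cond.shape[2] != length:
        raise ValueError("condition channels must match batch and length")
    y = np.concatenate([x.data, cond], axis=1)
    return _make(y, (x,), lambda g: x._accumulate(g[:, :c, :]))


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("shape mismatch in add")

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _make(a.data + b.data, (a, b), backward)


def bce_with_logits(scores: Tensor, target: float) -> Tensor:
    """Mean binary cross-entropy of sigmoid(scores) against a constant target.

    Computed in the numerically stable logit form
    ``softplus(s) - t * s`` averaged over every element.
    """
    s = scores.data
    loss = np.mean(np.logaddexp(0.0, s) - target * s)
    n = s.size

    def backward(g):
        p = 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
        scores._accumulate(g * (p - target) / n)

    return _make(loss, (scores,), backward)


def mse_to_constant(x: Tensor, target: float) -> Tensor:
    """Mean squared deviation from a constant target (least-squares GAN)."""
    diff = x.data - target
    n = diff.size
    return _make(np.mean(diff * diff), (x,),
                 lambda g: x._accumulate(g * 2.0 * diff / n))


def weighted_sum(x: Tensor, weights: np.ndarray) -> Tensor:
    """Scalar ``sum(x * weights)`` with constant weights.

    Used to backpropagate from a single output unit (receptive-field
    probing) by passing an indicator array.
    """
    w = np.asarray(weights, dtype=np.float64)
    return _make(np.sum(x.data * w), (x,), lambda g: x._accumulate(g * w))


def l1_mean(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute difference between two equally shaped tensors."""
    if a.data.shape != b.data.shape:
        raise ValueError("shape mismatch in l1_mean")
    diff = a.data - b.data
    n = diff.size
    sign = np.sign(diff)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * sign / n)
        if b.requires_grad:
            b._accumulate(-g * sign / n)

    return _make(np.mean(np.abs(diff)), (a, b), backward)


class Adam:
    """Adam optimizer over a list of :class:`Parameter`.

    Defaults follow the Keras convention: beta1=0.9, beta2=0.999,
    epsilon=1e-7.  The learning rate may be changed between steps (used
    by the generator schedule).
    """

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
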