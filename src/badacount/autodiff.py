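"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the differentiable-array engine behind the counting network: 2-D
convolution (with stride and dilation), max/average pooling, ReLU,
channel-softmax, concatenation, the gradient reversal layer, and the scalar
reductions used by the losses.  Tensors carry ``float64`` data; every
operation records a backward closure, and :meth:`Tensor.backward` runs a
topological sweep.  Parameters are plain Tensors with ``requires_grad=True``
updated by :class:`SGD`.

All computation is deterministic for fixed inputs and parameters; no
threading or stochastic kernels are involved.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "relu",
    "softplus",
    "softmax_channels",
    "concat_channels",
    "grad_reverse",
    "mean_abs_error",
    "binary_cross_entropy",
    "SGD",
]


class Tensor:
    """An array node in the autodiff graph.

    Parameters
    ----------
    data:
        Array content; stored as ``float64``.
    requires_grad:
        Whether gradients should be accumulated into :attr:`grad`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out._parents:

            def backward(g):
                _accum(self, _unbroadcast(g, self.data.shape))
                _accum(other, _unbroadcast(g, other.data.shape))

            out._backward = backward
        return out

    __radd__ = __add__

    def __sub__(self, other) -> "Tensor":
        return self + (as_tensor(other) * -1.0)

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (self * -1.0)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out._parents:
            a, b = self, other

            def backward(g):
                _accum(a, _unbroadcast(g * b.data, a.data.shape))
                _accum(b, _unbroadcast(g * a.data, b.data.shape))

            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out = _node(self.data**e, (self,))
        if out._parents:

            def backward(g):
                _accum(self, g * e * self.data ** (e - 1.0))

            out._backward = backward
        return out

    def sum(self) -> "Tensor":
        out = _node(self.data.sum(), (self,))
        if out._parents:

            def backward(g):
                _accum(self, np.broadcast_to(g, self.data.shape))

            out._backward = backward
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        return self.sum() * (1.0 / n)

    # -- backward sweep -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node.

        ``grad`` defaults to ones (a scalar loss seeds with 1.0).
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        }
        # temporarily route _accum through this dict
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                _ACCUM_STACK.append(grads)
                try:
                    node._backward(g)
                finally:
                    _ACCUM_STACK.pop()


_ACCUM_STACK: list[dict[int, np.ndarray]] = []


def _accum(node: Tensor, grad: np.ndarray) -> None:
    grads = _ACCUM_STACK[-1]
    key = id(node)
    if key in grads:
        grads[key] = grads[key] + grad
    else:
        grads[key] = grad


_GRAD_ENABLED = True


class no_grad:
    """Context manager suspending graph construction.

    Inside the context, operations return plain result Tensors with no
    recorded parents or backward closures — inference then costs no graph
    memory (the per-layer im2col buffers otherwise captured for the backward
    pass dominate the footprint of large inputs).
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _needs_grad(parents: Iterable[Tensor]) -> bool:
    return _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents)


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _needs_grad(parents):
        out._parents = tuple(parents)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding: int | None = None,
) -> Tensor:
    """2-D convolution (cross-correlation) over NCHW input.

    ``padding=None`` means "same" spatial size for stride 1 (half the
    effective kernel extent); the effective kernel extent with dilation ``d``
    is ``d*(k-1)+1``.
    """
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = weight.data.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input has {C}, weight expects {Cw}")
    keff_h = dilation * (kh - 1) + 1
    keff_w = dilation * (kw - 1) + 1
    if padding is None:
        padding = keff_h // 2
        if keff_h != keff_w:
            raise ValueError("auto-padding requires a square kernel")
    p = int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - keff_h) // stride + 1
    Wo = (Wp - keff_w) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d: input smaller than effective kernel")

    view = np.lib.stride_tricks.sliding_window_view(xp, (keff_h, keff_w), axis=(2, 3))
    patches = view[:, :, ::stride, ::stride, ::dilation, ::dilation]
    # (N, Ho, Wo, C*kh*kw) @ (C*kh*kw, O) via BLAS
    cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw
    )
    wmat = weight.data.reshape(O, C * kh * kw)
    out_data = (cols @ wmat.T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _node(np.ascontiguousarray(out_data), parents)
    if out._parents:

        def backward(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
            _accum(weight, (gmat.T @ cols).reshape(O, C, kh, kw))
            if bias is not None:
                _accum(bias, g.sum(axis=(0, 2, 3)))
            gxp = np.zeros((N, C, Hp, Wp))
            for u in range(kh):
                for v in range(kw):
                    # g (N,O,Ho,Wo) x W[:, :, u, v] (O,C) -> (N,C,Ho,Wo)
                    contrib = np.einsum("noij,oc->ncij", g, weight.data[:, :, u, v])
                    gxp[
                        :,
                        :,
                        u * dilation : u * dilation + Ho * stride : stride,
                        v * dilation : v * dilation + Wo * stride : stride,
                    ] += contrib
            _accum(x, gxp[:, :, p : Hp - p, p : Wp - p] if p else gxp)

        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# pooling and activations
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Max pooling with kernel == stride == ``k``; H, W must be divisible."""
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"max_pool2d: spatial size {(H, W)} not divisible by {k}")
    Ho, Wo = H // k, W // k
    blocks = x.data.reshape(N, C, Ho, k, Wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, Ho, Wo, k * k
    )
    idx = blocks.argmax(axis=-1)
    out = _node(np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0], (x,))
    if out._parents:

        def backward(g):
            gb = np.zeros((N, C, Ho, Wo, k * k))
            np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
            gx = gb.reshape(N, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
            _accum(x, gx)

        out._backward = backward
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Average pooling with kernel == stride == ``k``."""
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial size {(H, W)} not divisible by {k}")
    Ho, Wo = H // k, W // k
    out = _node(x.data.reshape(N, C, Ho, k, Wo, k).mean(axis=(3, 5)), (x,))
    if out._parents:

        def backward(g):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            _accum(x, gx)

        out._backward = backward
    return out


def softplus(x: Tensor) -> Tensor:
    """Smooth non-negativity activation log(1 + exp(x)).

    Used on count outputs instead of ReLU: its gradient never vanishes, so a
    count head cannot die into an all-zero prediction it can never leave.
    """
    out = _node(np.logaddexp(0.0, x.data), (x,))
    if out._parents:
        sig = 1.0 / (1.0 + np.exp(-x.data))

        def backward(g):
            _accum(x, g * sig)

        out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = _node(x.data * mask, (x,))
    if out._parents:

        def backward(g):
            _accum(x, g * mask)

        out._backward = backward
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (channels) of an NCHW tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    out = _node(p, (x,))
    if out._parents:

        def backward(g):
            dot = (g * p).sum(axis=1, keepdims=True)
            _accum(x, p * (g - dot))

        out._backward = backward
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two NCHW tensors along the channel axis."""
    if a.data.shape[2:] != b.data.shape[2:] or a.data.shape[0] != b.data.shape[0]:
        raise ValueError(
            f"concat_channels: incompatible shapes {a.data.shape} vs {b.data.shape}"
        )
    ca = a.data.shape[1]
    out = _node(np.concatenate([a.data, b.data], axis=1), (a, b))
    if out._parents:

        def backward(g):
            _accum(a, g[:, :ca])
            _accum(b, g[:, ca:])

        out._backward = backward
    return out


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Gradient reversal layer.

    Forward pass is the identity; the backward pass multiplies the upstream
    gradient by ``-lam``.  With ``lam == 0`` the layer blocks all gradient
    flow into ``x``, which freezes the feature extractor with respect to the
    adversarial loss while leaving the discriminators trainable.
    """
    lam = float(lam)
    if lam < 0:
        raise ValueError("grad_reverse: lambda must be >= 0")
    out = _node(x.data.copy(), (x,))
    if out._parents:

        def backward(g):
            _accum(x, -lam * g)

        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# scalar reductions
# ---------------------------------------------------------------------------

def mean_abs_error(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean of |pred - target| over all elements (L1 loss)."""
    target = np.asarray(target, dtype=np.float64)
    if pred.data.shape != target.shape:
        raise ValueError(
            f"mean_abs_error: shape mismatch {pred.data.shape} vs {target.shape}"
        )
    diff = pred.data - target
    out = _node(np.abs(diff).mean(), (pred,))
    if out._parents:

        def backward(g):
            _accum(pred, g * np.sign(diff) / diff.size)

        out._backward = backward
    return out


def binary_cross_entropy(p: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy of probabilities ``p`` against 0/1 targets.

    Probabilities are clamped to ``[eps, 1 - eps]`` before the logarithm.
    """
    target = np.asarray(target, dtype=np.float64)
    if p.data.shape != target.shape:
        raise ValueError(
            f"binary_cross_entropy: shape mismatch {p.data.shape} vs {target.shape}"
        )
    pc = np.clip(p.data, eps, 1.0 - eps)
    out = _node(-(target * np.log(pc) + (1.0 - target) * np.log1p(-pc)).mean(), (p,))
    if out._parents:
        inside = (p.data > eps) & (p.data < 1.0 - eps)

        def backward(g):
            grad = (pc - target) / (pc * (1.0 - pc)) / target.size
            _accum(p, g * grad * inside)

        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with classical momentum.

    ``v <- mu * v + grad``; ``p <- p - lr * v`` — the same update rule as
    torch's SGD with ``dampening=0``.
    """

    def __init__(self, params: Sequence[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("SGD: lr must be positive")
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
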