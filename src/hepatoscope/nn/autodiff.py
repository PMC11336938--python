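"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for small convolutional networks: broadcasting
arithmetic, matmul, stride-1 2-D convolution, pooling reductions and the
pointwise nonlinearities used by the classifier.  Every op builds a node
in a dynamic graph; :meth:`Tensor.backward` runs a topological sweep and
accumulates gradients into the leaves that require them.

Gradients of every op are verified against central finite differences in
the test suite; correctness is favoured over speed throughout (inputs
here are 15 x 30 images and cohorts of tens of subjects).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "instance_norm", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._backward = None
        self._parents = _parents

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)  # copy: g may alias a child's grad
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
            # Break the node<->closure reference cycle and drop gradients of
            # interior nodes so each training step's graph is freed promptly.
            if node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * Tensor(-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-out.grad * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = bw
        return out

    # -- pointwise nonlinearities --------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * e)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in ((axis,) if isinstance(axis, int) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False) -> "Tensor":
        """Maximum reduction; ties share the gradient equally."""
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(
            m, axis=axis if axis is not None else tuple(range(self.data.ndim))
        )
        out = Tensor(out_data, _parents=(self,))

        def bw():
            if not self.requires_grad:
                return
            g = out.grad
            if not keepdims:
                g = g.reshape(m.shape)
            mask = (self.data == m).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            self._accum(mask * g)

        out._backward = bw
        return out

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = bw
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), zero-padded.

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw); ``b``: (O,) or None.
    Computed as a sum of per-tap channel contractions (one einsum per
    kernel position) — transparent, exactly differentiable, and cheaper
    than materialising im2col windows at these tensor sizes.
    """
    N, C, H, W = x.shape
    O, C2, kh, kw = w.shape
    if C != C2:
        raise ValueError(f"input has {C} channels but kernel expects {C2}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho, Wo = H + 2 * p - kh + 1, W + 2 * p - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("kernel larger than padded input")
    out_data = np.zeros((N, O, Ho, Wo))
    for i in range(kh):
        for j in range(kw):
            out_data += np.einsum(
                "nchw,oc->nohw", xp[:, :, i : i + Ho, j : j + Wo], w.data[:, :, i, j]
            )
    if b is not None:
        out_data += b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bw():
        g = out.grad
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + Ho, j : j + Wo] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j]
                    )
            x._accum(dxp[:, :, p : p + H, p : p + W] if p else dxp)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    dw[:, :, i, j] = np.einsum(
                        "nohw,nchw->oc", g, xp[:, :, i : i + Ho, j : j + Wo]
                    )
            w._accum(dw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise to zero mean / unit variance over the spatial axes (2, 3).

    Fused primitive for the per-(sample, channel) normalisation used
    throughout the network; affine scale/shift stays outside.
    """
    axes = (2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    centred = x.data - mu
    var = (centred**2).mean(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = centred * inv_std
    out = Tensor(xhat, _parents=(x,))

    def bw():
        if not x.requires_grad:
            return
        g = out.grad
        g_mean = g.mean(axis=axes, keepdims=True)
        gx_mean = (g * xhat).mean(axis=axes, keepdims=True)
        x._accum(inv_std * (g - g_mean - xhat * gx_mean))

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of ``logits`` (N, K) against integer ``targets``.

    Fused and numerically stable (log-sum-exp with max subtraction); the
    gradient is the classic ``softmax - onehot`` averaged over the batch.
    """
    targets = np.asarray(targets, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = -log_probs[np.arange(n), targets].mean()
    out = Tensor(loss, _parents=(logits,))

    def bw():
        if logits.requires_grad:
            probs = np.exp(log_probs)
            probs[np.arange(n), targets] -= 1.0
            logits._accum(out.grad * probs / n)

    out._backward = bw
    return out
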