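"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small transformer: broadcast-aware
elementwise arithmetic, (batched) matmul, reshape/transpose/slice/concat,
GELU, softmax, layer norm, and fused mean-squared-error and
softmax-cross-entropy losses.  Gradients are accumulated on a tape and
propagated by topological sort.  Everything is gradient-checked against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cat", "softmax", "layer_norm", "gelu",
           "mse_loss", "cross_entropy_logits", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = ()
        self._backward = None

    # -- graph construction ------------------------------------------------
    @classmethod
    def _op(cls, data, parents, backward):
        out = cls(data)
        if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep the operand dtype: python scalars must not upcast float32
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        a, b = self.data, other.data
        out_data = a @ b
        need_a, need_b = self.requires_grad, other.requires_grad

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape) if need_a else None
            gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape) if need_b else None
            return (ga, gb)

        return Tensor._op(out_data, (self, other), backward)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        old_shape = self.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            return (g.reshape(old_shape),)

        return Tensor._op(out_data, (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            return (g.transpose(tuple(inv)),)

        return Tensor._op(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        return Tensor._op(out_data, (self,), backward)

    def broadcast_to(self, shape):
        out_data = np.broadcast_to(self.data, shape)

        def backward(g):
            return (_unbroadcast(g, self.shape),)

        return Tensor._op(out_data, (self,), backward)

    # -- autodiff driver ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if node._backward is None and g is not None and node._parents == ():
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if parent._parents or parent._backward:
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
                else:  # leaf parameter
                    parent.grad = pg if parent.grad is None else parent.grad + pg
        # leaves reached directly (self is a leaf): handled above


def cat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(out_data, tuple(tensors), backward)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    xd = x.data
    inner = xd * xd
    inner *= 0.044715
    inner += 1.0
    inner *= xd
    inner *= _GELU_C
    t = np.tanh(inner)
    half1pt = t + 1.0
    half1pt *= 0.5               # 0.5 * (1 + tanh(.))
    out_data = xd * half1pt

    def backward(g):
        sech2 = t * t
        np.subtract(1.0, sech2, out=sech2)
        dinner = xd * xd
        dinner *= 3.0 * 0.044715
        dinner += 1.0
        dinner *= _GELU_C
        sech2 *= dinner
        sech2 *= xd
        sech2 *= 0.5
        sech2 += half1pt
        sech2 *= g
        return (sech2,)

    return Tensor._op(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        out = g - dot
        out *= y
        return (out,)

    return Tensor._op(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    n = x.data.shape[-1]

    def backward(g):
        g_gamma = _unbroadcast(g * xhat, gamma.shape)
        g_beta = _unbroadcast(g, beta.shape)
        gx_hat = g * gamma.data
        gx = inv * (gx_hat
                    - gx_hat.mean(axis=-1, keepdims=True)
                    - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True))
        return (gx, g_gamma, g_beta)

    return Tensor._op(out_data, (x, gamma, beta), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error over all elements (target is a constant)."""
    target = np.asarray(target)
    diff = pred.data - target
    out_data = np.asarray((diff * diff).mean())
    scale = 2.0 / diff.size

    def backward(g):
        return (g * scale * diff,)

    return Tensor._op(out_data, (pred,), backward)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are 0-based class indices."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    out_data = np.asarray(-logp[np.arange(n), labels].mean())
    probs = np.exp(logp)

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        return (g * grad / n,)

    return Tensor._op(out_data, (logits,), backward)
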