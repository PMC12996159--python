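"""Reverse-mode automatic differentiation over numpy arrays.

The decoder network is small (~13k trainable scalars) and built from a
handful of dense array operations, so gradients are computed by a compact
tape-based engine rather than a deep-learning framework.  Every operation
records its parents and a closure that accumulates gradients; ``backward``
walks the tape in reverse topological order.  Correctness is pinned by a
finite-difference check in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "elu", "leaky_relu", "sigmoid", "softmax", "pad1d",
           "batch_norm_train", "log_window_variance", "gradcheck"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = np.asarray(data, dtype=dtype)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # store-by-reference on first touch, out-of-place add afterwards;
        # gradients are never mutated in place so aliasing is safe
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        if self.data.ndim < 2 or other.data.ndim < 2:
            raise ValueError("matmul requires >=2-D operands")
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._node(out_data, (self, other), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._node(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._node(out_data, (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            mask = (self.data == expanded).astype(self.data.dtype)
            mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)

        return self._node(out_data, (self,), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def clip_min(self, floor: float):
        """max(x, floor); gradient passes only where x > floor."""
        out_data = np.maximum(self.data, floor)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > floor))

        return self._node(out_data, (self,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accum(g * out_data * (1.0 - out_data))

    return Tensor._node(out_data, (x,), backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out_data = np.where(x.data > 0, x.data, neg)

    def backward(g):
        if x.requires_grad:
            x._accum(g * np.where(x.data > 0, 1.0, neg + alpha))

    return Tensor._node(out_data, (x,), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out_data = np.where(x.data > 0, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * np.where(x.data > 0, 1.0, slope))

    return Tensor._node(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilised softmax (max-shift is a constant w.r.t. grads)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple,
                     eps: float = 1e-5):
    """Fused batch normalisation (training statistics) with analytic backward.

    Returns ``(out, mean, var)`` where mean/var are plain arrays (keepdims)
    for the caller's running-statistics update.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    out_data = gamma.data * xhat + beta.data
    n = x.data.size // mu.size

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(
                _unbroadcast(g * xhat, gamma.data.shape).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape).reshape(beta.data.shape))
        if x.requires_grad:
            dxhat = g * gamma.data
            s1 = dxhat.sum(axis=axes, keepdims=True)
            s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
            x._accum(ivar * (dxhat - s1 / n - xhat * s2 / n))

    out = Tensor._node(out_data, (x, gamma, beta), backward)
    return out, mu, var


def log_window_variance(x: Tensor, w: int, eps: float) -> Tensor:
    """Fused log(max(population variance, eps)) over trailing windows of w
    samples: (..., t*w) -> (..., t)."""
    T = x.shape[-1]
    t = T // w
    xw = x.data[..., : t * w].reshape(*x.data.shape[:-1], t, w)
    mu = xw.mean(axis=-1, keepdims=True)
    centred = xw - mu
    var = (centred ** 2).mean(axis=-1)
    clipped = np.maximum(var, eps)
    out_data = np.log(clipped)

    def backward(g):
        if not x.requires_grad:
            return
        coeff = np.where(var > eps, g / clipped, 0.0)
        dx = (2.0 / w) * centred * coeff[..., None]
        if t * w != T:
            dx = np.concatenate(
                [dx.reshape(*x.data.shape[:-1], t * w),
                 np.zeros((*x.data.shape[:-1], T - t * w), dtype=dx.dtype)],
                axis=-1)
        else:
            dx = dx.reshape(x.data.shape)
        x._accum(dx)

    return Tensor._node(out_data, (x,), backward)


def pad1d(x: Tensor, before: int, after: int, axis: int = -1) -> Tensor:
    """Zero-pad along one axis."""
    widths = [(0, 0)] * x.data.ndim
    widths[axis] = (before, after)
    out_data = np.pad(x.data, widths)
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(before, before + x.data.shape[axis])
    sl = tuple(sl)

    def backward(g):
        if x.requires_grad:
            x._accum(g[sl])

    return Tensor._node(out_data, (x,), backward)


def gradcheck(fn, params: list[Tensor], n_samples: int = 50, eps: float = 1e-6,
              seed: int = 0) -> float:
    """Compare tape gradients of the scalar ``fn()`` against central
    finite differences on randomly sampled parameter entries.

    ``fn`` must be free of side effects (it is re-evaluated many times).
    Returns the worst relative error over entries whose gradient magnitude
    exceeds finite-difference noise (1e-6).
    """
    for p in params:
        p.grad = None
    fn().backward()
    grads = [None if p.grad is None else np.array(p.grad, dtype=np.float64)
             for p in params]

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_samples):
        i = int(rng.integers(len(params)))
        p = params[i]
        idx = tuple(int(rng.integers(s)) for s in p.data.shape)
        orig = p.data[idx]
        p.data[idx] = orig + eps
        hi = float(fn().data)
        p.data[idx] = orig - eps
        lo = float(fn().data)
        p.data[idx] = orig
        fd = (hi - lo) / (2 * eps)
        ad = 0.0 if grads[i] is None else float(grads[i][idx])
        denom = max(abs(fd), abs(ad))
        if denom < 1e-6:
            continue  # below finite-difference noise floor
        worst = max(worst, abs(fd - ad) / denom)
    return worst
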