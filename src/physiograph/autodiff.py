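"""Reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core of the package: a small tape-based autodiff
engine sufficient for the graph/recurrent/variational networks defined in
:mod:`physiograph.pgin_core`, :mod:`physiograph.pgin_heads` and
:mod:`physiograph.ahsim`, together with an Adam optimizer and a finite
difference gradient checker.

Design notes
------------
* A :class:`Var` wraps an ``ndarray`` value and accumulates ``grad`` during
  :meth:`Var.backward`.  Broadcasting follows NumPy semantics; gradients of
  broadcast operands are summed back to the operand shape.
* Only the operations the models need are implemented.  Anything missing
  should be composed from these primitives rather than special-cased.
* The tape is built eagerly; ``backward`` runs a topological sweep.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Var",
    "as_var",
    "concat",
    "stack",
    "softmax",
    "log_softmax",
    "Adam",
    "finite_difference_grad",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation tape holding a value and (later) a gradient."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(
        self,
        value,
        parents: tuple = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = True,
        name: str = "",
    ):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad
        self.name = name

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" '{self.name}'" if self.name else ""
        return f"Var{tag}(shape={self.value.shape})"

    # -- autodiff ----------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=float), self.value.shape)
        # grads are stored by reference and never mutated in place, so an
        # array shared between two parents stays consistent
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | float | None = None) -> None:
        """Backpropagate from this node; seeds with ones for scalars by default."""
        topo: list[Var] = []
        seen: set[int] = set()
        stack_: list[tuple[Var, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        if grad is None:
            grad = np.ones_like(self.value)
        self._accum(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_var(other)
        out = Var(self.value + other.value, (self, other))

        def bwd(g):
            self._accum(g)
            other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Var(-self.value, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_var(other))

    def __rsub__(self, other):
        return as_var(other) + (-self)

    def __mul__(self, other):
        other = as_var(other)
        out = Var(self.value * other.value, (self, other))

        def bwd(g):
            self._accum(g * other.value)
            other._accum(g * self.value)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_var(other)
        out = Var(self.value / other.value, (self, other))

        def bwd(g):
            self._accum(g / other.value)
            other._accum(-g * self.value / other.value**2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_var(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = Var(self.value**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.value ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_var(other)
        out = Var(self.value @ other.value, (self, other))

        def bwd(g):
            a, b = self.value, other.value
            if a.ndim == 1 and b.ndim == 1:  # inner product
                self._accum(g * b)
                other._accum(g * a)
                return
            if a.ndim == 1:
                ga = (b * g[..., None, :]).sum(-1)
                self._accum(_unbroadcast(ga, a.shape))
                other._accum(_unbroadcast(a[:, None] * g[..., None, :], b.shape))
                return
            if b.ndim == 1:
                self._accum(_unbroadcast(g[..., None] * b, a.shape))
                other._accum(_unbroadcast((a * g[..., None]).sum(-2), b.shape))
                return
            self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = bwd
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        val = np.exp(self.value)
        out = Var(val, (self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Var(np.log(self.value), (self,))
        out._backward = lambda g: self._accum(g / self.value)
        return out

    def sqrt(self):
        val = np.sqrt(self.value)
        out = Var(val, (self,))
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def tanh(self):
        val = np.tanh(self.value)
        out = Var(val, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - val**2))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))
        out = Var(val, (self,))
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def relu(self):
        mask = self.value > 0
        out = Var(self.value * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.value > lo
        out = Var(np.where(mask, self.value, lo), (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Var(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.value.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.value.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.value.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.value.shape
        out = Var(self.value.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def swapaxes(self, a: int, b: int):
        out = Var(np.swapaxes(self.value, a, b), (self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = Var(self.value[idx], (self,))
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, np.integer, slice, type(Ellipsis))) for p in parts)

        def bwd(g):
            full = np.zeros_like(self.value)
            if basic:  # disjoint selection: plain assignment is safe and fast
                full[idx] = g
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out


def as_var(x) -> Var:
    """Wrap plain arrays/scalars as constant (still differentiable-through) Vars."""
    if isinstance(x, Var):
        return x
    return Var(np.asarray(x, dtype=float))


def concat(vars_: Sequence[Var], axis: int = -1) -> Var:
    vars_ = [as_var(v) for v in vars_]
    vals = [v.value for v in vars_]
    out = Var(np.concatenate(vals, axis=axis), tuple(vars_))
    sizes = [v.shape[axis] for v in vals]
    offs = np.cumsum([0] + sizes)

    def bwd(g):
        for v, a, b in zip(vars_, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(a, b)
            v._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(vars_: Sequence[Var], axis: int = 0) -> Var:
    vars_ = [as_var(v) for v in vars_]
    out = Var(np.stack([v.value for v in vars_], axis=axis), tuple(vars_))

    def bwd(g):
        for i, v in enumerate(vars_):
            v._accum(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def softmax(x: Var, axis: int = -1) -> Var:
    x = as_var(x)
    val = x.value - x.value.max(axis=axis, keepdims=True)
    e = np.exp(val)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Var(s, (x,))

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    out._backward = bwd
    return out


def log_softmax(x: Var, axis: int = -1) -> Var:
    x = as_var(x)
    shifted = x.value - x.value.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    ls = shifted - lse
    out = Var(ls, (x,))

    def bwd(g):
        x._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer with optional decoupled weight decay."""

    def __init__(
        self,
        params: Iterable[Var],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)


def finite_difference_grad(
    loss_fn: Callable[[], Var], param: Var, indices, h: float = 1e-5
) -> np.ndarray:
    """Central finite differences of ``loss_fn`` w.r.t. selected entries of ``param``.

    ``indices`` is an iterable of flat indices into ``param.value``.  Used as the
    independent check of the tape gradients.
    """
    flat = param.value.reshape(-1)
    idx_list = list(indices)
    grads = np.empty(len(idx_list))
    for n, i in enumerate(idx_list):
        orig = flat[i]
        flat[i] = orig + h
        lp = float(loss_fn().value)
        flat[i] = orig - h
        lm = float(loss_fn().value)
        flat[i] = orig
        grads[n] = (lp - lm) / (2 * h)
    return grads
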