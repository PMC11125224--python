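"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in this package is small (a few graph-convolution stacks over
``(batch, channel, frame, node)`` tensors), so rather than depending on a
deep-learning framework the package carries its own tape-based autodiff:
a :class:`Tensor` wraps an ``ndarray`` and records the operation that
produced it; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients.

Only the primitives the model needs are provided: broadcasting
arithmetic, ``einsum`` (the workhorse of every graph convolution),
elementwise nonlinearities, reductions, shape ops, padding/slicing and a
numerically guarded ``clip``. All computation is float64.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "einsum",
    "relu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "clip",
    "pad_time",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # collapse axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode gradients."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], tuple[np.ndarray | None, ...]] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward_fn = backward_fn if self.requires_grad else None

    # ------------------------------------------------------------------ misc
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (per-epoch chains)
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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            node.grad = g if node.grad is None else node.grad + g
            if node._backward_fn is not None:
                parent_grads = node._backward_fn(g)
                for p, pg in zip(node._parents, parent_grads):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            parents=(self, other),
            backward_fn=lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, parents=(self,), backward_fn=lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a * b,
            parents=(self, other),
            backward_fn=lambda g: (
                _unbroadcast(g * b, a.shape),
                _unbroadcast(g * a, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor(
            a / b,
            parents=(self, other),
            backward_fn=lambda g: (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            ),
        )

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        a = self.data
        return Tensor(
            a**p,
            parents=(self,),
            backward_fn=lambda g: (g * p * a ** (p - 1),),
        )

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self.data
        out = a.sum(axis=axis, keepdims=keepdims)

        def back(g: np.ndarray):
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor(out, parents=(self,), backward_fn=back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self.data
        n = a.size if axis is None else np.prod(
            [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- shape ops
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self.data
        return Tensor(
            a.reshape(shape),
            parents=(self,),
            backward_fn=lambda g: (g.reshape(a.shape),),
        )

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        return Tensor(
            self.data.transpose(axes),
            parents=(self,),
            backward_fn=lambda g: (g.transpose(inv),),
        )

    def __getitem__(self, idx) -> "Tensor":
        a = self.data

        def back(g: np.ndarray):
            out = np.zeros_like(a)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(a[idx], parents=(self,), backward_fn=back)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- elementwise
def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), backward_fn=lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, parents=(x,), backward_fn=lambda g: (g * s * (1.0 - s),))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return Tensor(t, parents=(x,), backward_fn=lambda g: (g * (1.0 - t * t),))


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    return Tensor(e, parents=(x,), backward_fn=lambda g: (g * e,))


def log(x: Tensor) -> Tensor:
    a = x.data
    return Tensor(np.log(a), parents=(x,), backward_fn=lambda g: (g / a,))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with pass-through gradient inside the interval (zero outside)."""
    a = x.data
    mask = (a >= lo) & (a <= hi)
    return Tensor(np.clip(a, lo, hi), parents=(x,), backward_fn=lambda g: (g * mask,))


# -------------------------------------------------------------------- einsum
def einsum(spec: str, *operands: Tensor) -> Tensor:
    """Differentiable einsum for 1-3 operands.

    Restriction (sufficient for every layer here): no repeated index inside
    a single operand, and every index of each operand appears in the output
    or in another operand — the gradient is then itself an einsum.
    """
    ops = [as_tensor(o) for o in operands]
    ins, out_sub = spec.replace(" ", "").split("->")
    subs = ins.split(",")
    if len(subs) != len(ops):
        raise ValueError("einsum spec does not match operand count")
    out = np.einsum(spec, *[o.data for o in ops], optimize=True)

    def back(g: np.ndarray):
        grads = []
        for i, (sub_i, op_i) in enumerate(zip(subs, ops)):
            if not op_i.requires_grad:
                grads.append(None)
                continue
            other_subs = [out_sub] + [s for j, s in enumerate(subs) if j != i]
            other_arrs = [g] + [o.data for j, o in enumerate(ops) if j != i]
            gspec = ",".join(other_subs) + "->" + sub_i
            grads.append(np.einsum(gspec, *other_arrs, optimize=True))
        return tuple(grads)

    return Tensor(out, parents=tuple(ops), backward_fn=back)


# ------------------------------------------------------------------- padding
def pad_time(x: Tensor, before: int, after: int, axis: int = 2) -> Tensor:
    """Zero-pad one axis (the frame axis by default)."""
    widths = [(0, 0)] * x.ndim
    widths[axis] = (before, after)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(before, before + x.shape[axis])
    sl = tuple(sl)
    return Tensor(
        np.pad(x.data, widths),
        parents=(x,),
        backward_fn=lambda g: (g[sl],),
    )


# ------------------------------------------------------------------- softmax
def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is treated as a constant,
    which is exact because softmax is shift-invariant."""
    shift = np.max(logits.data, axis=axis, keepdims=True)
    e = exp(logits - Tensor(shift))
    return e / e.sum(axis=axis, keepdims=True)
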